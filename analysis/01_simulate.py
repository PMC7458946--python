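"""Generate the synthetic audit/inspection dataset.

Produces the default 8-year (2011-2018) program: ~86.7 activities per
year, ~13% inspections, ~5.9 findings per activity, with per-CIF
presence rates matching the configured base rates.  Writes
activities.csv / studies.csv / sites.csv / truth.json under
<out>/data/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import make_config, parse_args

from cifrisk import CIFS
from cifrisk.cif import finding_column
from cifrisk.pipeline import read_tables, stage_simulate


def main() -> None:
    args = parse_args(__doc__)
    cfg = make_config(args)
    data_dir = stage_simulate(cfg)
    act, studies, sites = read_tables(data_dir)
    cols = [finding_column(c) for c in CIFS]
    total = act[cols].to_numpy().sum()
    print(f"wrote {data_dir}")
    print(f"{len(act)} activities over {act['year'].nunique()} years "
          f"({len(act) / act['year'].nunique():.1f}/year), "
          f"{(act['activity_type'] == 'inspection').mean():.1%} inspections")
    print(f"{total} findings total, {total / len(act):.2f} per activity")
    print(f"{len(studies)} studies, {len(sites)} sites")
    for c in CIFS:
        print(f"  presence rate {c}: {(act[finding_column(c)] >= 1).mean():.3f}")


if __name__ == "__main__":
    main()
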