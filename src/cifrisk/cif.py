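"""The Clinical Impact Factor (CIF) taxonomy.

Audit and inspection findings are grouped into five quality-risk
categories, each attached to one of two GCP impact areas: protection of
human subjects, or reliability of trial results.  One binary risk model
is fitted per CIF.
"""

# Order matters: it is the canonical column / reporting order.
CIFS: tuple[str, ...] = (
    "consent",
    "safety",
    "data_integrity",
    "protecting_primary_endpoints",
    "sponsor_oversight",
)

CIF_AREAS: dict[str, str] = {
    "consent": "human_subject_protection",
    "safety": "human_subject_protection",
    "data_integrity": "reliability_of_trial_results",
    "protecting_primary_endpoints": "reliability_of_trial_results",
    "sponsor_oversight": "reliability_of_trial_results",
}

#: Activity-level column name holding the finding count for a CIF.
def finding_column(cif: str) -> str:
    if cif not in CIFS:
        raise ValueError(f"unknown CIF {cif!r}; expected one of {CIFS}")
    return f"finding_{cif}"
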