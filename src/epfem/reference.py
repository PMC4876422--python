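"""Packaged reference data.

``reference_fit_summary`` returns the published per-sequence calibration
summary of the ex vivo beef-liver study this model was fitted to: for each
of the nine pulse sequences, the maximum measured current I_MAX and the
average current deviation avg dI (absolute and relative) for the
per-sequence-optimised run (Run1) and the shared-parameter run (Run2).
"""

from __future__ import annotations

import csv
from importlib import resources

__all__ = ["reference_fit_summary", "default_params_path"]

_COLUMNS = ("sequence", "i_max_A", "run1_avg_dI_A", "run1_rel_pct",
            "run2_avg_dI_A", "run2_rel_pct")


def reference_fit_summary() -> list[dict]:
    """Per-sequence reference fit table as a list of dicts (floats)."""
    path = resources.files("epfem.data") / "reference_fit_summary.csv"
    with path.open() as fh:
        rows = list(csv.DictReader(fh))
    out = []
    for row in rows:
        rec = {k: float(row[k]) for k in _COLUMNS}
        rec["sequence"] = int(rec["sequence"])
        out.append(rec)
    return out


def default_params_path():
    """Path-like handle of the packaged default parameter file."""
    return resources.files("epfem.data") / "default_params.yaml"
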