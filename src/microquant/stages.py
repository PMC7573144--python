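"""Four-stage nucleocytoplasmic translocation classification.

A cell's stage is decided from its area-normalised nuclear (``N_nuc``) and
cytoplasmic (``N_cyt``) signal against the background-control thresholds
``B_nuc`` / ``B_cyt`` measured on no-primary-antibody fields:

* ``none``     — N_cyt <= B_cyt (signal, if any, confined to the nucleus);
* ``severe``   — N_cyt > B_cyt and N_nuc <= B_nuc (nucleus cleared);
* ``mild``     — N_cyt > B_cyt, N_nuc > B_nuc and N_cyt < N_nuc;
* ``moderate`` — N_cyt > B_cyt, N_nuc > B_nuc and N_cyt >= N_nuc.

Ties: "above threshold" is strict, "below threshold" inclusive, and the
nuclear-vs-cytoplasmic tie N_cyt = N_nuc counts as moderate (mild requires
the cytoplasmic signal to be strictly below the nuclear one).  The mapping
is total and mutually exclusive on every input with a defined N_cyt.
"""

from __future__ import annotations

import pandas as pd

from .quantify import BackgroundControl, CellRecord
from .synthetic import STAGES

STAGE_ORDER = {s: i for i, s in enumerate(STAGES)}


def classify_stage(rec: CellRecord, bg: BackgroundControl) -> str:
    """Stage of one cell; raises on an empty cytoplasm (undefined N_cyt)."""
    n_cyt = rec.N_cyt
    if n_cyt is None:
        raise ValueError(f"cell {rec.label}: zero cytoplasm area, stage undefined")
    return classify_values(rec.N_nuc, n_cyt, bg.B_nuc, bg.B_cyt)


def classify_values(n_nuc: float, n_cyt: float, b_nuc: float, b_cyt: float) -> str:
    if n_cyt <= b_cyt:
        return "none"
    if n_nuc <= b_nuc:
        return "severe"
    return "mild" if n_cyt < n_nuc else "moderate"


def stage_counts(records: list[tuple[str, str]]) -> pd.DataFrame:
    """Condition x stage contingency table of cell counts.

    ``records`` is a list of (condition, stage) pairs; every listed
    condition appears as a row and all four stages as columns, so row sums
    equal the number of classified cells per condition.
    """
    df = pd.DataFrame(records, columns=["condition", "stage"])
    conditions = list(dict.fromkeys(df["condition"])) if len(df) else []
    table = pd.DataFrame(0, index=conditions, columns=list(STAGES), dtype=int)
    for (cond, stage), n in df.value_counts().items():
        table.loc[cond, stage] = n
    table.index.name = "condition"
    return table


def whole_cell_intensity(records: list[CellRecord]) -> list[float]:
    """Area-normalised whole-cell AF647 series used for between-condition
    comparisons (SUM over the body divided by body area)."""
    return [r.N_cell for r in records]
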