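"""Point-biserial screening of each variable against the outcome.

The published analysis shows the linear correlation of every variable with
the further-fracture outcome before the evolutionary selection, noting that
all |r| are small and that the selection nevertheless keeps variables with
near-zero linear correlation (menopause age, r ≈ −0.033) — the motivation
for a non-linear classifier.  The point-biserial coefficient is the Pearson
r between a numeric variable and the 0/1 outcome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = ["pointbiserial_screen"]


def pointbiserial_screen(table: CohortTable) -> pd.DataFrame:
    """Pearson r of each variable with the binary outcome, ranked by |r|.

    Returns a frame with columns ``variable``, ``r`` (full precision),
    ``r_3dp`` and ``rank`` (1 = largest |r|).

    Raises
    ------
    ValueError
        If the outcome is single-class, or a variable is constant (its
        correlation is undefined); the error names the offending column.
    """
    y = table.y.astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; correlations undefined")
    rows = []
    yc = y - y.mean()
    for name in table.variable_names:
        x = table.frame[name].to_numpy(dtype=float)
        xc = x - x.mean()
        denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        if denom == 0:
            raise ValueError(f"variable {name!r} is constant; correlation undefined")
        rows.append({"variable": name, "r": float(xc @ yc / denom)})
    out = pd.DataFrame(rows)
    out["r_3dp"] = out["r"].round(3)
    out["rank"] = out["r"].abs().rank(ascending=False, method="first").astype(int)
    return out.sort_values("rank").reset_index(drop=True)
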