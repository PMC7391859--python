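"""Cross-measurement comparison of random effects.

When several measurements are modelled on the same subjects, the
correlation of one random-effect component's BLUPs across measurements
says whether individuals are consistently large/small (size), early/late
(timing) or fast/slow (intensity).  Seriation reorders the correlation
matrix so strongly associated measurements sit next to each other —
implemented, per its usual gloss, as ranking by median correlation with
the other measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import value_at_age
from .model import EFFECTS, SitarFit

__all__ = [
    "EffectCorrelationMatrix",
    "cross_measure_correlations",
    "seriate",
    "size_percent_sd",
]

_EFFECT_COL = {"size": "alpha", "timing": "beta", "intensity": "gamma"}


@dataclass
class EffectCorrelationMatrix:
    """Pairwise BLUP correlations of one effect across measurements."""

    effect: str
    measurements: list
    matrix: pd.DataFrame      # square, unit diagonal; NaN where too few shared subjects
    pair_n: pd.DataFrame      # shared-subject counts

    @property
    def median_offdiagonal(self) -> float:
        vals = self.matrix.to_numpy()
        off = vals[~np.eye(len(vals), dtype=bool)]
        return float(np.nanmedian(off))

    def is_complete(self) -> bool:
        return not self.matrix.isna().any().any()


def cross_measure_correlations(fits: dict, effect: str) -> EffectCorrelationMatrix:
    """Pearson correlations of one effect's BLUPs over shared subjects.

    Pairs with fewer than 3 shared subjects get a missing entry.
    """
    if effect not in EFFECTS:
        raise ValueError(f"unknown effect {effect!r}")
    if len(fits) < 2:
        raise ValueError("need at least two fitted measurements")
    col = _EFFECT_COL[effect]
    names = list(fits)
    series = {
        m: fits[m].blup_frame().set_index("id")[col] for m in names
    }
    k = len(names)
    mat = np.full((k, k), np.nan)
    cnt = np.zeros((k, k), dtype=int)
    for i in range(k):
        mat[i, i] = 1.0
        cnt[i, i] = len(series[names[i]])
        for j in range(i + 1, k):
            a, b = series[names[i]].align(series[names[j]], join="inner")
            cnt[i, j] = cnt[j, i] = len(a)
            if len(a) >= 3:
                r = float(np.corrcoef(a.to_numpy(), b.to_numpy())[0, 1])
                mat[i, j] = mat[j, i] = r
    return EffectCorrelationMatrix(
        effect=effect,
        measurements=names,
        matrix=pd.DataFrame(mat, index=names, columns=names),
        pair_n=pd.DataFrame(cnt, index=names, columns=names),
    )


def seriate(ecm: EffectCorrelationMatrix) -> tuple[list, EffectCorrelationMatrix]:
    """Reorder measurements by descending median correlation with the rest.

    A pure permutation: the multiset of matrix entries is unchanged.
    Ties break on measurement name.
    """
    if not ecm.is_complete():
        raise ValueError("correlation matrix has missing entries; cannot seriate")
    vals = ecm.matrix.to_numpy()
    k = len(vals)
    med = np.array([np.median(np.delete(vals[i], i)) for i in range(k)])
    order = sorted(range(k), key=lambda i: (-med[i], ecm.measurements[i]))
    names = [ecm.measurements[i] for i in order]
    reordered = EffectCorrelationMatrix(
        effect=ecm.effect,
        measurements=names,
        matrix=ecm.matrix.iloc[order, order],
        pair_n=ecm.pair_n.iloc[order, order],
    )
    return names, reordered


def size_percent_sd(fit: SitarFit, at_age: float = 19.0) -> float:
    """Size random-effect SD as a percent of the mean-curve value at 19.

    The proportional scale makes size variability comparable across
    measurements of very different magnitude.
    """
    return 100.0 * float(np.sqrt(fit.re_cov[0, 0])) / value_at_age(fit, at_age)
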