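"""ROC analysis of simple DECT parameters and ROD similarity markers.

AUC is the normalized Mann-Whitney statistic (ties count one half): the
probability that a random positive outscores a random negative under the
marker's orientation.  Simple node parameters are higher-is-positive
(metastatic nodes enhance more); ROD markers are lower-is-positive (a
metastatic node resembles its primary, so its ROD is small).

The operating threshold maximizes Youden's J = sensitivity + specificity - 1
over midpoints between adjacent distinct scores; classification is
``score >= threshold`` for higher-is-positive markers and ``<= threshold``
for lower-is-positive ones.  J-ties are broken toward the more sensitive
operating point, matching the screening role of the markers.  Thresholds are
reported in the marker's native units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "DiagnosticsError",
    "Marker",
    "DiagnosticResult",
    "roc_auc",
    "optimal_threshold",
    "evaluate_markers",
    "default_markers",
]

HIGHER = "higher-is-positive"
LOWER = "lower-is-positive"


class DiagnosticsError(ValueError):
    """Invalid diagnostic input."""


@dataclass(frozen=True)
class Marker:
    """A scored marker column and its orientation."""

    column: str
    orientation: str = HIGHER
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.orientation not in (HIGHER, LOWER):
            raise DiagnosticsError(f"unknown orientation {self.orientation!r}")


@dataclass(frozen=True)
class DiagnosticResult:
    """Per-marker, per-stratum ROC summary (percent sens/spec)."""

    marker: str
    stratum: str
    orientation: str
    auc: float
    threshold: float
    sensitivity_pct: float
    specificity_pct: float
    n_positive: int
    n_negative: int
    degenerate: bool = False
    unevaluable: bool = False

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "stratum": self.stratum,
            "orientation": self.orientation,
            "auc": self.auc,
            "threshold": self.threshold,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "degenerate": self.degenerate,
            "unevaluable": self.unevaluable,
        }


def _validate(scores, labels) -> Tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size != y.size:
        raise DiagnosticsError("scores and labels differ in length")
    if not set(np.unique(y)) <= {0, 1}:
        raise DiagnosticsError("labels must be binary 0/1")
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise DiagnosticsError("both classes must be present")
    return s, y


def roc_auc(scores, labels, orientation: str = HIGHER) -> float:
    """AUC under the given orientation (ties count half)."""
    s, y = _validate(scores, labels)
    if orientation == LOWER:
        s = -s
    elif orientation != HIGHER:
        raise DiagnosticsError(f"unknown orientation {orientation!r}")
    if np.ptp(s) == 0:
        return 0.5  # constant marker: chance
    return float(roc_auc_score(y, s))


def optimal_threshold(
    scores, labels, orientation: str = HIGHER
) -> Tuple[float, float, float]:
    """Youden-optimal threshold and its sensitivity/specificity (percent).

    Candidate cuts are midpoints between adjacent distinct scores plus a cut
    outside the observed range on either side; ties on J favor the more
    sensitive operating point.
    """
    s, y = _validate(scores, labels)
    if orientation not in (HIGHER, LOWER):
        raise DiagnosticsError(f"unknown orientation {orientation!r}")
    distinct = np.unique(s)
    if distinct.size == 1:
        cands = np.array([distinct[0]])
    else:
        mids = (distinct[:-1] + distinct[1:]) / 2.0
        span = distinct[-1] - distinct[0]
        cands = np.concatenate(
            [[distinct[0] - 0.5 * span], mids, [distinct[-1] + 0.5 * span]]
        )
    pos = s[y == 1]
    neg = s[y == 0]
    if orientation == HIGHER:
        sens = (pos[:, None] >= cands[None, :]).mean(axis=0)
        spec = (neg[:, None] < cands[None, :]).mean(axis=0)
    else:
        sens = (pos[:, None] <= cands[None, :]).mean(axis=0)
        spec = (neg[:, None] > cands[None, :]).mean(axis=0)
    j = sens + spec - 1.0
    best_j = j.max()
    tied = np.flatnonzero(j >= best_j - 1e-12)
    # among J-ties prefer higher sensitivity, then higher specificity
    order = np.lexsort((spec[tied], sens[tied]))
    pick = tied[order[-1]]
    return float(cands[pick]), float(100.0 * sens[pick]), float(100.0 * spec[pick])


def default_markers() -> List[Marker]:
    """The study's marker panel: five simple node parameters, five RODs."""
    simple = [
        Marker("node_att40_hu", HIGHER, "Attenuation at 40 keV"),
        Marker("node_att70_hu", HIGHER, "Attenuation at 70 keV"),
        Marker("lambda_hu_node", HIGHER, "lambda-HU"),
        Marker("node_ic_mgcm3", HIGHER, "IC"),
        Marker("node_effz", HIGHER, "Eff-Z"),
    ]
    rods = [
        Marker("rod_att40", LOWER, "ROD of attenuation at 40 keV"),
        Marker("rod_att70", LOWER, "ROD of attenuation at 70 keV"),
        Marker("rod_lambda", LOWER, "ROD of lambda-HU"),
        Marker("rod_ic", LOWER, "ROD of IC"),
        Marker("rod_effz", LOWER, "ROD of Eff-Z"),
    ]
    return simple + rods


def evaluate_markers(
    cohort: pd.DataFrame,
    markers: Optional[Sequence[Marker]] = None,
    subgroup: Optional[pd.Series] = None,
    stratum: str = "full",
    label_col: str = "group",
) -> List[DiagnosticResult]:
    """One :class:`DiagnosticResult` per marker on a cohort stratum.

    ``subgroup`` is an optional boolean row filter (e.g. small nodes,
    ``cohort["node_short_mm"] < 5``).  A stratum with a single outcome class
    yields results flagged ``unevaluable``; a constant marker yields AUC 0.5
    flagged ``degenerate``.
    """
    if markers is None:
        markers = default_markers()
    data = cohort if subgroup is None else cohort.loc[np.asarray(subgroup, dtype=bool)]
    y = data[label_col].to_numpy(dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    out: List[DiagnosticResult] = []
    for m in markers:
        if m.column not in data.columns:
            raise DiagnosticsError(f"marker column {m.column!r} not in cohort")
        name = m.label or m.column
        if n_pos == 0 or n_neg == 0:
            out.append(
                DiagnosticResult(
                    marker=name, stratum=stratum, orientation=m.orientation,
                    auc=float("nan"), threshold=float("nan"),
                    sensitivity_pct=float("nan"), specificity_pct=float("nan"),
                    n_positive=n_pos, n_negative=n_neg, unevaluable=True,
                )
            )
            continue
        s = data[m.column].to_numpy(dtype=float)
        degenerate = np.ptp(s) == 0
        auc = roc_auc(s, y, m.orientation)
        thr, sens, spec = optimal_threshold(s, y, m.orientation)
        out.append(
            DiagnosticResult(
                marker=name, stratum=stratum, orientation=m.orientation,
                auc=auc, threshold=thr, sensitivity_pct=sens,
                specificity_pct=spec, n_positive=n_pos, n_negative=n_neg,
                degenerate=bool(degenerate),
            )
        )
    return out
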