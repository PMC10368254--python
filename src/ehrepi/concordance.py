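"""Lin's concordance correlation coefficient for validating estimate series.

The CCC measures agreement between two series x (reference) and y
(candidate) as

    rho_c = 2 * s_xy / (s_x^2 + s_y^2 + (m_x - m_y)^2)

penalising both loss of correlation and shifts in location or scale.  It
equals the Pearson correlation multiplied by a bias-correction factor in
(0, 1], so |rho_c| <= |r| with equality only when the two series share
mean and variance.  Moments default to the population (1/n) convention;
a sample (1/(n-1)) variant is available.

Confidence intervals use the Fisher z-transform with Lin's asymptotic
variance, the conventional large-sample interval for this estimator.
Interpretation bands: < 0.90 poor, [0.90, 0.95) moderate, [0.95, 0.99)
substantial, >= 0.99 almost perfect.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class Interpretation(str, enum.Enum):
    poor = "poor"
    moderate = "moderate"
    substantial = "substantial"
    almost_perfect = "almost_perfect"


@dataclass
class PairedSeries:
    """Aligned reference/candidate pairs, joined on a shared label
    (disease name or calendar year)."""

    labels: list[str]
    x: np.ndarray  # reference values
    y: np.ndarray  # candidate values
    dropped: list[str] = field(default_factory=list)
    scale_note: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.labels) != self.x.size or self.x.size != self.y.size:
            raise ValueError("labels, x and y must have equal length")
        if self.x.size < 2:
            raise ValueError("insufficient pairs: need at least 2")
        if np.isnan(self.x).any() or np.isnan(self.y).any():
            raise ValueError("aligned series must not contain missing values")

    @property
    def n(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class ConcordanceResult:
    ccc: float
    ci_lower: float
    ci_upper: float
    n: int
    interpretation: Interpretation


_MISSING_TOKENS = {"", "na", "n/a", "nan", "not available", "none"}


def _is_missing(v: object) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return isinstance(v, str) and v.strip().lower() in _MISSING_TOKENS


def align_series(
    a: dict[str, object], b: dict[str, object], scale_note: str = ""
) -> PairedSeries:
    """Inner-join two labelled value maps into a paired series.

    Pairs where either side is missing (absent label, ``None``, NaN or a
    textual placeholder such as "Not available") are dropped and recorded
    in ``dropped``.  Fewer than 2 surviving pairs is an error.
    """
    labels: list[str] = []
    xs: list[float] = []
    ys: list[float] = []
    dropped: list[str] = []
    for label in a:
        if label not in b or _is_missing(a[label]) or _is_missing(b[label]):
            dropped.append(str(label))
            continue
        labels.append(str(label))
        xs.append(float(a[label]))
        ys.append(float(b[label]))
    dropped.extend(str(label) for label in b if label not in a)
    if len(labels) < 2:
        raise ValueError(
            f"insufficient pairs: {len(labels)} shared non-missing label(s)"
        )
    return PairedSeries(labels, np.array(xs), np.array(ys), dropped, scale_note)


def _moments(
    x: np.ndarray, y: np.ndarray, moments: str
) -> tuple[float, float, float, float, float]:
    if moments not in {"population", "sample"}:
        raise ValueError("moments must be 'population' or 'sample'")
    ddof = 0 if moments == "population" else 1
    mx, my = float(np.mean(x)), float(np.mean(y))
    sx2 = float(np.var(x, ddof=ddof))
    sy2 = float(np.var(y, ddof=ddof))
    sxy = float(np.sum((x - mx) * (y - my)) / (x.size - ddof))
    return mx, my, sx2, sy2, sxy


def lins_ccc(s: PairedSeries, moments: str = "population") -> float:
    """Lin's concordance correlation coefficient, in [-1, 1].

    Raises when both series are constant with equal means (0/0: agreement
    is undefined, not perfect).
    """
    mx, my, sx2, sy2, sxy = _moments(s.x, s.y, moments)
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        raise ValueError("CCC undefined: both series constant with equal means")
    return 2.0 * sxy / denom


def ccc_confidence_interval(
    s: PairedSeries,
    level: float = 0.95,
    moments: str = "population",
) -> tuple[float, float]:
    """Fisher z-transform confidence interval with Lin's asymptotic variance.

    A coefficient of exactly +/-1 gives the degenerate interval [ccc, ccc].
    """
    ccc = lins_ccc(s, moments)
    n = s.n
    if abs(ccc) >= 1.0:
        return ccc, ccc
    if n < 3:
        raise ValueError("confidence interval requires at least 3 pairs")
    mx, my, sx2, sy2, sxy = _moments(s.x, s.y, moments)
    if sx2 == 0.0 or sy2 == 0.0:
        raise ValueError("confidence interval undefined for a constant series")
    r = sxy / math.sqrt(sx2 * sy2)
    u2 = (mx - my) ** 2 / math.sqrt(sx2 * sy2)  # squared location shift, u^2
    c2 = ccc**2
    # Lin's large-sample variance of z = atanh(rho_c)
    var_z = (
        (1 - r**2) * c2 / ((1 - c2) * r**2)
        + 2 * ccc**3 * (1 - ccc) * u2 / (r * (1 - c2) ** 2)
        - ccc**4 * u2**2 / (2 * r**2 * (1 - c2) ** 2)
    ) / (n - 2)
    se_z = math.sqrt(max(var_z, 0.0))
    z = math.atanh(ccc)
    q = stats.norm.ppf(0.5 + level / 2.0)
    return math.tanh(z - q * se_z), math.tanh(z + q * se_z)


def interpret_ccc(ccc: float) -> Interpretation:
    """Map a coefficient to its agreement band."""
    if not -1.0 <= ccc <= 1.0:
        raise ValueError("CCC must lie in [-1, 1]")
    if ccc >= 0.99:
        return Interpretation.almost_perfect
    if ccc >= 0.95:
        return Interpretation.substantial
    if ccc >= 0.90:
        return Interpretation.moderate
    return Interpretation.poor


def concordance(
    s: PairedSeries, level: float = 0.95, moments: str = "population"
) -> ConcordanceResult:
    """CCC, confidence interval and interpretation band in one result."""
    ccc = lins_ccc(s, moments)
    lower, upper = ccc_confidence_interval(s, level, moments)
    return ConcordanceResult(
        ccc=ccc,
        ci_lower=lower,
        ci_upper=upper,
        n=s.n,
        interpretation=interpret_ccc(ccc),
    )
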