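"""Monte Carlo propagation of fraction-corrected concentrations to Er/RI.

The deterministic fraction-modified Hakanson assessment is turned into a
probabilistic one in three steps:

1. per metal, fit a normal or lognormal distribution to the fraction-
   corrected concentrations observed across sites (Shapiro–Wilk selects
   the family, boxplot screening removes gross outliers first);
2. draw a large number of corrected concentrations per metal (metals
   independent), fold each draw above background via the secondary
   correction, and push it through the contamination factor and hazard
   index arithmetic, summing across metals into RI per draw;
3. summarize the draws as class probabilities against the re-derived
   grading schemes, percentile bands, empirical CDFs, and
   contribution-to-variance sensitivities (normalized squared Spearman
   rank correlation of each metal's Er draws with RI).

Because the secondary correction folds the sampled distribution at the
background value, analytic checks of the class probabilities must fold
the input CDF the same way; :func:`folded_class_probability` provides the
closed form used as an oracle in the test-suite.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import BackgroundSet, ClassificationScheme, ToxicityParams
from .indices import derive_er_scheme, derive_ri_scheme

logger = logging.getLogger("fracrisk")

__all__ = [
    "DistributionSpec",
    "MonteCarloResult",
    "screen_outliers",
    "fit_distribution",
    "propagate",
    "class_probabilities",
    "cumulative_curve",
    "sensitivity_contributions",
    "folded_class_probability",
]


@dataclass(frozen=True)
class DistributionSpec:
    """Fitted distribution of one metal's corrected concentration.

    ``family`` is ``"normal"`` (loc = mean, scale = sd on the raw scale),
    ``"lognormal"`` (loc = mean, scale = sd of the logs), or ``"point"``
    (a degenerate distribution at ``loc``, used for what-if analyses).
    """

    metal: str
    family: str
    loc: float
    scale: float
    sw_p_raw: float | None = None
    sw_p_log: float | None = None
    outliers_removed: tuple[str, ...] = ()
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal", "point"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "point":
            if self.scale != 0:
                raise ValueError("point family requires scale == 0")
        elif not (math.isfinite(self.scale) and self.scale > 0):
            raise ValueError(f"scale must be > 0, got {self.scale!r}")
        if self.family == "lognormal" and not math.isfinite(self.loc):
            raise ValueError("lognormal log-mean must be finite")

    def mean(self) -> float:
        """Mean on the concentration scale."""
        if self.family == "lognormal":
            return math.exp(self.loc + 0.5 * self.scale**2)
        return self.loc


def screen_outliers(xs, labels=None):
    """Boxplot screening: flag values outside [Q1 − 1.5 IQR, Q3 + 1.5 IQR].

    Returns ``(retained_values, retained_labels, flagged_labels)``; the
    retained values preserve input order.  With fewer than four
    observations no screening is done (a warning is logged).
    """
    xs = np.asarray(xs, dtype=float)
    if labels is None:
        labels = [str(i) for i in range(len(xs))]
    labels = list(labels)
    if len(labels) != len(xs):
        raise ValueError("labels must match values one-to-one")
    if len(xs) < 4:
        logger.warning("only %d observations: skipping outlier screening", len(xs))
        return xs.copy(), labels, []
    q1, q3 = np.percentile(xs, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (xs >= lo) & (xs <= hi)
    flagged = [lab for lab, k in zip(labels, keep) if not k]
    retained_labels = [lab for lab, k in zip(labels, keep) if k]
    return xs[keep], retained_labels, flagged


def fit_distribution(
    xs,
    alpha: float = 0.05,
    metal: str = "",
    labels=None,
    screen: bool = True,
) -> DistributionSpec:
    """Select and fit a normal or lognormal distribution via Shapiro–Wilk.

    Raw values are tested first; if they pass at ``alpha`` the normal
    family is fitted by sample mean and sd.  Otherwise the log values are
    tested; if they pass, a lognormal is fitted by the mean and sd of the
    logs.  If neither passes, the family with the larger p-value is used
    and a warning is attached to the returned spec.
    """
    xs = np.asarray(xs, dtype=float)
    outliers: tuple[str, ...] = ()
    if screen:
        xs, _, flagged = screen_outliers(xs, labels)
        outliers = tuple(flagged)
    n = len(xs)
    if n < 8:
        raise ValueError(f"need >= 8 observations after screening, got {n}")
    if np.ptp(xs) == 0:
        raise ValueError("degenerate (constant) sample: cannot fit a distribution")

    # scipy warns above n = 5000 that the SW p-value may be inaccurate;
    # the decision only needs p relative to alpha, so that is acceptable.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_raw = float(stats.shapiro(xs).pvalue)
        p_log: float | None = None
        if np.all(xs > 0):
            p_log = float(stats.shapiro(np.log(xs)).pvalue)

    if p_raw >= alpha:
        family, warn = "normal", None
    elif p_log is not None and p_log >= alpha:
        family, warn = "lognormal", None
    elif p_log is None:
        family = "normal"
        warn = "normality rejected and non-positive values preclude a lognormal"
    else:
        family = "normal" if p_raw >= p_log else "lognormal"
        warn = (
            f"neither family passed Shapiro–Wilk at alpha={alpha} "
            f"(raw p={p_raw:.3g}, log p={p_log:.3g}); using the better fit"
        )
    if warn:
        logger.warning("%s: %s", metal or "sample", warn)

    if family == "normal":
        loc, scale = float(np.mean(xs)), float(np.std(xs, ddof=1))
    else:
        lx = np.log(xs)
        loc, scale = float(np.mean(lx)), float(np.std(lx, ddof=1))
    return DistributionSpec(
        metal=metal,
        family=family,
        loc=loc,
        scale=scale,
        sw_p_raw=p_raw,
        sw_p_log=p_log,
        outliers_removed=outliers,
        warning=warn,
    )


@dataclass
class MonteCarloResult:
    """Propagated Er/RI draws with their summaries."""

    n_draws: int
    seed: int
    er_samples: dict[str, np.ndarray]
    ri_samples: np.ndarray
    percentiles: dict[str, dict[str, float]]  # metal or "RI" -> {"p2.5", "p50", "p97.5"}
    class_probs: dict[str, dict[str, float]]  # metal or "RI" -> label -> probability
    sensitivity: dict[str, float] = field(default_factory=dict)  # metal -> % of RI variance
    rejected_draws: dict[str, int] = field(default_factory=dict)


def _sample_concentrations(
    spec: DistributionSpec, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Draw n concentrations; negative normal draws are rejected and redrawn."""
    if spec.family == "point":
        return np.full(n, spec.loc), 0
    if spec.family == "lognormal":
        return rng.lognormal(spec.loc, spec.scale, size=n), 0
    out = rng.normal(spec.loc, spec.scale, size=n)
    rejected = 0
    bad = out < 0
    while bad.any():
        rejected += int(bad.sum())
        out[bad] = rng.normal(spec.loc, spec.scale, size=int(bad.sum()))
        bad = out < 0
    return out, rejected


def propagate(
    specs: dict[str, DistributionSpec],
    backgrounds: BackgroundSet,
    tox: ToxicityParams,
    er_scheme: ClassificationScheme | None = None,
    ri_scheme: ClassificationScheme | None = None,
    n: int = 50_000,
    seed: int = 0,
) -> MonteCarloResult:
    """Monte Carlo propagation of per-metal corrected-concentration specs.

    Per draw and metal: sample the corrected concentration, fold it above
    background (secondary correction), form Cf and Er; RI per draw is the
    sum of Er across metals.  Metals are sampled independently.  The same
    seed and specs reproduce the result exactly.
    """
    if n < 1000:
        raise ValueError("need at least 1000 draws")
    missing = [
        m
        for m in specs
        if m not in backgrounds.values or m not in tox.tr
    ]
    if missing:
        raise ValueError(
            "no background and/or toxicity value for: " + ", ".join(missing)
        )
    er_scheme = er_scheme or derive_er_scheme(tox)
    ri_scheme = ri_scheme or derive_ri_scheme(tox)

    rng = np.random.default_rng(seed)
    er_samples: dict[str, np.ndarray] = {}
    rejected: dict[str, int] = {}
    ri = np.zeros(n)
    for metal in sorted(specs):  # fixed order => seed determinism
        spec = specs[metal]
        c0 = backgrounds[metal]
        draws, nrej = _sample_concentrations(spec, n, rng)
        folded = np.abs(draws - c0) + c0
        er = tox.tr[metal] * folded / c0
        er_samples[metal] = er
        ri += er
        rejected[metal] = nrej
        if nrej:
            logger.info("%s: %d negative draws rejected and redrawn", metal, nrej)

    percentiles = {}
    class_probs = {}
    for metal, er in er_samples.items():
        p = np.percentile(er, [2.5, 50, 97.5])
        percentiles[metal] = {"p2.5": p[0], "p50": p[1], "p97.5": p[2]}
        class_probs[metal] = class_probabilities(er, er_scheme)
    p = np.percentile(ri, [2.5, 50, 97.5])
    percentiles["RI"] = {"p2.5": p[0], "p50": p[1], "p97.5": p[2]}
    class_probs["RI"] = class_probabilities(ri, ri_scheme)

    result = MonteCarloResult(
        n_draws=n,
        seed=seed,
        er_samples=er_samples,
        ri_samples=ri,
        percentiles=percentiles,
        class_probs=class_probs,
        rejected_draws=rejected,
    )
    if np.var(ri) > 0:
        result.sensitivity = sensitivity_contributions(result)
    return result


def class_probabilities(
    samples, scheme: ClassificationScheme
) -> dict[str, float]:
    """Empirical probability per half-open class interval; sums to 1."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("need at least one sample")
    # searchsorted(side="right") puts a sample equal to a boundary in the
    # upper interval, matching the classify() convention.
    idx = np.searchsorted(np.asarray(scheme.boundaries), samples, side="right")
    counts = np.bincount(idx, minlength=len(scheme.labels))
    return {
        label: counts[i] / samples.size for i, label in enumerate(scheme.labels)
    }


def cumulative_curve(samples) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF over the sorted unique sample values.

    Returns ``(values, cumulative_probability)``; the CDF at the largest
    value is exactly 1.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("need at least one sample")
    values, counts = np.unique(samples, return_counts=True)
    cum = np.cumsum(counts) / samples.size
    return values, cum


def sensitivity_contributions(result: MonteCarloResult) -> dict[str, float]:
    """Contribution-to-variance of each metal's Er draws to the RI draws.

    Computed as the squared Spearman rank correlation of each metal's Er
    samples with the RI samples, normalized so the contributions sum to
    100%.
    """
    ri = result.ri_samples
    if np.var(ri) == 0:
        raise ValueError("RI samples have zero variance")
    raw: dict[str, float] = {}
    for metal, er in result.er_samples.items():
        if np.var(er) == 0:
            raw[metal] = 0.0
            continue
        rho = stats.spearmanr(er, ri).statistic
        raw[metal] = float(rho) ** 2
    total = sum(raw.values())
    if total == 0:
        raise ValueError("all per-metal Er samples are constant")
    return {m: 100.0 * v / total for m, v in raw.items()}


def folded_class_probability(
    spec: DistributionSpec,
    c0: float,
    tr: float,
    scheme: ClassificationScheme,
) -> dict[str, float]:
    """Closed-form class probabilities of Er under the secondary fold.

    For a sampled concentration X, Er = tr * (|X − c0| + c0) / c0, so
    P(Er < b) = P(c0 (2 − b/tr) < X < c0 b/tr) for b/tr > 1 and 0
    otherwise.  Used as an analytic oracle against :func:`propagate`.
    """
    if spec.family == "lognormal":
        dist = stats.lognorm(s=spec.scale, scale=math.exp(spec.loc))
        p_neg = 0.0
    elif spec.family == "normal":
        # Negative draws are rejected in propagate(), so the effective
        # sampling distribution is the normal truncated at zero.
        dist = stats.norm(loc=spec.loc, scale=spec.scale)
        p_neg = float(dist.cdf(0.0))
    else:
        raise ValueError("point specs have no continuous CDF")

    def trunc_cdf(t: float) -> float:
        if t <= 0:
            return 0.0
        return (float(dist.cdf(t)) - p_neg) / (1.0 - p_neg)

    def cdf_er(b: float) -> float:
        r = b / tr
        if r <= 1.0:
            return 0.0
        return trunc_cdf(c0 * r) - trunc_cdf(c0 * (2.0 - r))

    probs = {}
    prev = 0.0
    for label, b in zip(scheme.labels, scheme.boundaries):
        cur = cdf_er(b)
        probs[label] = cur - prev
        prev = cur
    probs[scheme.labels[-1]] = 1.0 - prev
    return probs
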