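"""Deterministic contamination and ecological hazard indices.

Two families of index are computed per site and metal:

* the geoaccumulation index, Igeo = log2(Cn / (1.5 Bn)), against a
  geochemical background Bn;
* the Hakanson potential ecological hazard indices: a contamination
  factor Cf = C / C0 scaled by a metal-specific toxicity response value
  Tr into a single hazard index Er = Tr * Cf, summed across metals into
  the comprehensive index RI = sum(Er).

In *classic* mode Cf uses the total concentration directly.  In
*modified* mode the concentration is first replaced by a fraction-weighted
corrected concentration Cr = θ1 F1 + θ2 (F2 + F3) + θ3 F4, which weights
the mobile BCR fractions above the residual one, and then folded above the
background by the secondary correction Cr' = |Cr − C0| + C0 so that every
corrected concentration is at least the background (hence Cf >= 1 and
Er >= Tr).

Because the modified index is built from a six-metal set rather than
Hakanson's original eight pollutants, the class boundaries are re-derived:
the lowest Er boundary is the largest Tr in the set (the unpolluted value
of Er), the lowest RI boundary rescales the original lowest RI limit by
the ratio of toxicity sums, and higher boundaries follow the conventional
doubling progression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .core import (
    IGEO_SCHEME,
    RISK_LABELS,
    BackgroundSet,
    ClassificationScheme,
    FractionVector,
    HakansonConstants,
    SiteRecord,
    ToxicityParams,
    classify,
)

__all__ = [
    "MetalRisk",
    "SiteRiskResult",
    "geoaccumulation_index",
    "corrected_concentration",
    "secondary_correction",
    "contamination_factor",
    "single_hazard_index",
    "comprehensive_index",
    "assess_site",
    "derive_er_scheme",
    "derive_ri_scheme",
]


def geoaccumulation_index(cn: float, bn: float) -> float:
    """Igeo = log2(cn / (1.5 * bn)).

    ``cn`` is the measured concentration (mg/kg), ``bn`` the geochemical
    background (mg/kg); both must be strictly positive.
    """
    if not (math.isfinite(cn) and cn > 0):
        raise ValueError(f"measured concentration must be > 0, got {cn!r}")
    if not (math.isfinite(bn) and bn > 0):
        raise ValueError(f"background must be > 0, got {bn!r}")
    return math.log2(cn / (1.5 * bn))


def corrected_concentration(
    fv: FractionVector, theta: tuple[float, float, float]
) -> float:
    """Fraction-weighted corrected concentration θ1 F1 + θ2 (F2 + F3) + θ3 F4."""
    t1, t2, t3 = theta
    return (
        t1 * fv.f1_acid_soluble
        + t2 * (fv.f2_reducible + fv.f3_oxidizable)
        + t3 * fv.f4_residual
    )


def secondary_correction(cri: float, c0: float) -> float:
    """Fold the corrected concentration above background: |cri − c0| + c0.

    Guarantees the result is >= c0, so the downstream contamination factor
    is >= 1 as the Hakanson grading assumes.
    """
    if not (math.isfinite(c0) and c0 > 0):
        raise ValueError(f"background must be > 0, got {c0!r}")
    if not (math.isfinite(cri) and cri >= 0):
        raise ValueError(f"corrected concentration must be >= 0, got {cri!r}")
    return abs(cri - c0) + c0


def contamination_factor(c: float, c0: float) -> float:
    """Contamination factor Cf = c / c0."""
    if not (math.isfinite(c0) and c0 > 0):
        raise ValueError(f"background must be > 0, got {c0!r}")
    if not (math.isfinite(c) and c >= 0):
        raise ValueError(f"concentration must be >= 0, got {c!r}")
    return c / c0


def single_hazard_index(cf: float, tr: float) -> float:
    """Single potential ecological hazard index Er = Tr * Cf."""
    if not (math.isfinite(tr) and tr > 0):
        raise ValueError(f"toxicity response value must be > 0, got {tr!r}")
    if not (math.isfinite(cf) and cf >= 0):
        raise ValueError(f"contamination factor must be >= 0, got {cf!r}")
    return tr * cf


def comprehensive_index(ers) -> float:
    """Comprehensive potential ecological hazard index RI = sum of Er."""
    ers = list(ers)
    if not ers:
        raise ValueError("need at least one Er value")
    if any(not math.isfinite(e) for e in ers):
        raise ValueError("all Er values must be finite")
    return sum(ers)


def _double_from(lowest: float, n_classes: int) -> tuple[float, ...]:
    # n_classes labels need n_classes - 1 boundaries: lowest, 2*lowest, ...
    return tuple(lowest * 2.0**k for k in range(n_classes - 1))


def derive_er_scheme(tox: ToxicityParams, n_classes: int = 5) -> ClassificationScheme:
    """Re-derive the Er grading for the assessed metal set.

    The lowest class boundary is the largest toxicity response value in the
    set (the Er of an uncontaminated site for the most toxic metal, since
    Cf = 1 there); higher boundaries double.
    """
    if n_classes < 2:
        raise ValueError("need at least two classes")
    lowest = max(tox.tr.values())
    labels = _risk_labels(n_classes)
    return ClassificationScheme(
        kind="er", labels=labels, boundaries=_double_from(lowest, n_classes)
    )


def derive_ri_scheme(
    tox: ToxicityParams,
    hk: HakansonConstants = HakansonConstants(),
    n_classes: int = 5,
) -> ClassificationScheme:
    """Re-derive the RI grading via the unit toxicity coefficient.

    The original lowest RI limit divided by the original eight-pollutant
    toxicity sum gives the unit toxicity coefficient; multiplying by the
    assessed set's toxicity sum and rounding to the nearest multiple of ten
    gives the new lowest RI boundary; higher boundaries double.
    """
    if n_classes < 2:
        raise ValueError("need at least two classes")
    total = tox.toxicity_sum
    if total <= 0:
        raise ValueError("toxicity sum must be > 0")
    raw = hk.unit_toxicity_coefficient * total
    lowest = 10.0 * round(raw / 10.0)
    if lowest <= 0:
        # rounding to tens is meaningful only at the survey's scale; tiny
        # toxicity sums keep the unrounded limit instead of collapsing to 0
        lowest = raw
    labels = _risk_labels(n_classes)
    return ClassificationScheme(
        kind="ri", labels=labels, boundaries=_double_from(lowest, n_classes)
    )


def _risk_labels(n_classes: int) -> tuple[str, ...]:
    if n_classes == len(RISK_LABELS):
        return RISK_LABELS
    if n_classes < len(RISK_LABELS):
        return RISK_LABELS[: n_classes - 1] + (RISK_LABELS[-1],)
    extra = tuple(f"class {i}" for i in range(len(RISK_LABELS), n_classes))
    return RISK_LABELS[:-1] + extra + (RISK_LABELS[-1],)


@dataclass
class MetalRisk:
    """Per-metal index results of one site assessment."""

    metal: str
    igeo: float | None = None
    pollution_degree: str | None = None
    cr_corrected: float | None = None  # fraction-weighted Cr (modified mode)
    cr_secondary: float | None = None  # folded Cr' (modified mode)
    cf: float = float("nan")
    er: float = float("nan")
    risk_class: str = ""


@dataclass
class SiteRiskResult:
    """All index results of one site under one assessment mode."""

    site_id: str
    mode: str  # "classic" | "modified"
    metals: dict[str, MetalRisk] = field(default_factory=dict)
    ri: float = float("nan")
    ri_class: str = ""


def assess_site(
    site: SiteRecord,
    backgrounds: BackgroundSet,
    tox: ToxicityParams,
    mode: str = "modified",
    er_scheme: ClassificationScheme | None = None,
    ri_scheme: ClassificationScheme | None = None,
    igeo_scheme: ClassificationScheme = IGEO_SCHEME,
    metals=None,
) -> SiteRiskResult:
    """Assess one site: Igeo, Cf, Er per metal and the comprehensive RI.

    ``mode="classic"`` uses the total concentrations directly (requires
    totals for every assessed metal); ``mode="modified"`` uses the
    fraction-weighted corrected concentration with the secondary fold
    (requires a :class:`FractionVector` for every assessed metal).
    Metals default to those named in ``tox.tr``.
    """
    if mode not in ("classic", "modified"):
        raise ValueError(f"mode must be 'classic' or 'modified', got {mode!r}")
    metal_list = list(metals) if metals is not None else sorted(tox.tr)
    missing = []
    for m in metal_list:
        if m not in tox.tr:
            missing.append(f"{m}: no toxicity response value")
        if m not in backgrounds.values:
            missing.append(f"{m}: no background value")
        if mode == "classic" and m not in site.totals:
            missing.append(f"{m}: classic mode needs a total concentration")
        if mode == "modified" and m not in site.fractions:
            missing.append(f"{m}: modified mode needs BCR fractions")
    if missing:
        raise ValueError(
            f"site {site.site_id}: cannot assess in {mode} mode — "
            + "; ".join(missing)
        )

    er_scheme = er_scheme or derive_er_scheme(tox)
    ri_scheme = ri_scheme or derive_ri_scheme(tox)

    result = SiteRiskResult(site_id=site.site_id, mode=mode)
    ers = []
    for m in metal_list:
        c0 = backgrounds[m]
        mr = MetalRisk(metal=m)
        total = site.totals.get(m)
        if total is not None and total > 0:
            mr.igeo = geoaccumulation_index(total, c0)
            mr.pollution_degree = classify(mr.igeo, igeo_scheme)
        if mode == "classic":
            mr.cf = contamination_factor(total, c0)
        else:
            mr.cr_corrected = corrected_concentration(site.fractions[m], tox.theta)
            mr.cr_secondary = secondary_correction(mr.cr_corrected, c0)
            mr.cf = contamination_factor(mr.cr_secondary, c0)
        mr.er = single_hazard_index(mr.cf, tox.tr[m])
        mr.risk_class = classify(mr.er, er_scheme)
        ers.append(mr.er)
        result.metals[m] = mr
    result.ri = comprehensive_index(ers)
    result.ri_class = classify(result.ri, ri_scheme)
    return result
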