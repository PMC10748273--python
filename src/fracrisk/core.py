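"""Domain types, study constants, and risk-class schemes.

The package assesses soil heavy-metal pollution from both total
concentrations and BCR sequential-extraction fractions (acid/water-soluble
F1, reducible F2, oxidizable F3, residual F4).  Everything downstream —
the geoaccumulation index, the Hakanson hazard indices, and the Monte
Carlo propagation — is expressed over the small set of types defined here.

Metals are an open set keyed by their symbol so the machinery is reusable
beyond the six study metals (Cr, Ni, Cu, Zn, As, Pb); the study's own
parameter bundles ship as module-level constants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

logger = logging.getLogger("fracrisk")

#: Symbols of the six metals of the motivating survey.
STUDY_METALS: tuple[str, ...] = ("Cr", "Ni", "Cu", "Zn", "As", "Pb")

#: Names of the four BCR sequential-extraction fractions.
FRACTION_NAMES: tuple[str, ...] = ("F1", "F2", "F3", "F4")

#: Soil physicochemical property columns understood by the I/O layer.
PROPERTY_NAMES: tuple[str, ...] = ("SOM", "pH", "TN", "TP", "TK", "AN", "AP", "AK")


@dataclass(frozen=True)
class FractionVector:
    """BCR fraction concentrations (mg/kg) of one metal at one site.

    f1_acid_soluble is the most bioavailable and mobile fraction,
    f2_reducible is Fe–Mn-oxide bound, f3_oxidizable is organic/sulfide
    bound, and f4_residual is locked in the mineral lattice.
    """

    f1_acid_soluble: float
    f2_reducible: float
    f3_oxidizable: float
    f4_residual: float

    def __post_init__(self) -> None:
        for name, v in zip(FRACTION_NAMES, self.as_tuple()):
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"fraction {name} must be finite and >= 0, got {v!r}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (
            self.f1_acid_soluble,
            self.f2_reducible,
            self.f3_oxidizable,
            self.f4_residual,
        )

    @property
    def fraction_sum(self) -> float:
        return sum(self.as_tuple())


#: Relative fraction/total mass-balance disagreement beyond which a warning
#: is emitted (never a rejection).  Default mirrors the spread of BCR
#: recovery experiments (~96–105%) with headroom.
DEFAULT_MASS_BALANCE_TOLERANCE = 0.15


@dataclass
class SiteRecord:
    """One sampling point: totals, fraction vectors, physicochemical properties.

    ``totals`` maps metal symbol -> total concentration (mg/kg).
    ``fractions`` maps metal symbol -> :class:`FractionVector` and may cover
    only a subset of the metals.  ``properties`` holds soil physicochemical
    measurements (SOM g/kg, pH unitless, nutrient contents as configured).
    """

    site_id: str
    totals: dict[str, float] = field(default_factory=dict)
    fractions: dict[str, FractionVector] = field(default_factory=dict)
    properties: dict[str, float] = field(default_factory=dict)
    mass_balance_tolerance: float = DEFAULT_MASS_BALANCE_TOLERANCE

    def __post_init__(self) -> None:
        if not self.site_id:
            raise ValueError("site_id must be non-empty")
        for metal, v in self.totals.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"site {self.site_id}: total for {metal} must be finite "
                    f"and >= 0, got {v!r}"
                )
        ph = self.properties.get("pH")
        if ph is not None and not (0.0 < ph < 14.0):
            raise ValueError(f"site {self.site_id}: pH must lie in (0, 14), got {ph!r}")
        self._check_mass_balance()

    def _check_mass_balance(self) -> None:
        # Advisory only: the assessment never discards a site over
        # fraction/total disagreement.
        for metal, fv in self.fractions.items():
            total = self.totals.get(metal)
            if total is None or total <= 0:
                continue
            rel = abs(fv.fraction_sum / total - 1.0)
            if rel > self.mass_balance_tolerance:
                logger.warning(
                    "site %s, metal %s: fraction sum %.4g departs from total "
                    "%.4g by %.1f%% (tolerance %.0f%%)",
                    self.site_id,
                    metal,
                    fv.fraction_sum,
                    total,
                    100 * rel,
                    100 * self.mass_balance_tolerance,
                )


@dataclass(frozen=True)
class BackgroundSet:
    """Named set of geochemical background values (mg/kg) per metal."""

    provenance: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        for metal, v in self.values.items():
            if not (math.isfinite(v) and v > 0):
                raise ValueError(
                    f"background for {metal} must be finite and > 0, got {v!r}"
                )

    def __getitem__(self, metal: str) -> float:
        try:
            return self.values[metal]
        except KeyError:
            raise KeyError(
                f"background set {self.provenance!r} has no value for {metal}"
            ) from None

    def covers(self, metals) -> bool:
        return all(m in self.values for m in metals)


@dataclass(frozen=True)
class ToxicityParams:
    """Toxicity response values Tr per metal plus the fraction weights θ.

    θ = (θ1, θ2, θ3) weight the acid-soluble, (reducible + oxidizable),
    and residual fractions in the corrected concentration; mobile fractions
    carry more weight than the residual one, so θ1 > θ2 > θ3 > 0.
    """

    tr: dict[str, float]
    theta: tuple[float, float, float] = (1.6, 1.0, 0.6)

    def __post_init__(self) -> None:
        if not self.tr:
            raise ValueError("tr must name at least one metal")
        for metal, v in self.tr.items():
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"Tr for {metal} must be finite and > 0, got {v!r}")
        t1, t2, t3 = self.theta
        if not (t1 > t2 > t3 > 0):
            raise ValueError(f"theta must satisfy θ1 > θ2 > θ3 > 0, got {self.theta}")

    @property
    def toxicity_sum(self) -> float:
        return sum(self.tr.values())


@dataclass(frozen=True)
class HakansonConstants:
    """Constants of the original eight-pollutant Hakanson grading scheme.

    ``original_ri_lowest_limit`` is the lowest RI class boundary of the
    original method; ``original_toxicity_sum`` is the sum of the eight
    original toxicity response coefficients.  Their ratio is the "unit
    toxicity coefficient" used to rescale the RI grading to a different
    pollutant set.
    """

    original_ri_lowest_limit: float = 150.0
    original_toxicity_sum: float = 133.0

    def __post_init__(self) -> None:
        if self.original_ri_lowest_limit <= 0 or self.original_toxicity_sum <= 0:
            raise ValueError("Hakanson constants must be > 0")

    @property
    def unit_toxicity_coefficient(self) -> float:
        return self.original_ri_lowest_limit / self.original_toxicity_sum


@dataclass(frozen=True)
class ClassificationScheme:
    """Ordered risk/pollution classes over half-open numeric intervals.

    With boundaries (b1 < b2 < ... < bk) and k+1 labels, a value v is
    classified into the interval (−∞, b1), [b1, b2), ..., [bk, ∞): every
    interval owns its lower edge.
    """

    kind: str  # "igeo" | "er" | "ri"
    labels: tuple[str, ...]
    boundaries: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("igeo", "er", "ri"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if len(self.labels) != len(self.boundaries) + 1:
            raise ValueError(
                f"need len(labels) == len(boundaries) + 1, got "
                f"{len(self.labels)} labels and {len(self.boundaries)} boundaries"
            )
        if not self.boundaries:
            raise ValueError("at least one boundary is required")
        for lo, hi in zip(self.boundaries, self.boundaries[1:]):
            if not lo < hi:
                raise ValueError(f"boundaries must be strictly increasing: {self.boundaries}")
        if any(not math.isfinite(b) for b in self.boundaries):
            raise ValueError("boundaries must be finite")


def classify(value: float, scheme: ClassificationScheme) -> str:
    """Return the class label of the half-open interval containing ``value``.

    A value equal to a boundary belongs to the interval whose lower edge it
    is (the upper interval).
    """
    if not math.isfinite(value):
        raise ValueError(f"cannot classify non-finite value {value!r}")
    idx = 0
    for b in scheme.boundaries:
        if value >= b:
            idx += 1
        else:
            break
    return scheme.labels[idx]


# ---------------------------------------------------------------------------
# Study parameter bundles
# ---------------------------------------------------------------------------

#: Shaanxi provincial soil background values (mg/kg); used as the reference
#: for the geoaccumulation index and for the Hakanson contamination factors.
SHAANXI_BACKGROUND = BackgroundSet(
    provenance="Shaanxi",
    values={"Cr": 67.0, "Ni": 33.9, "Cu": 26.4, "Zn": 72.2, "As": 14.10, "Pb": 17.0},
)

#: Chinese national soil background values (mg/kg), CNEMC (1990); used only
#: as the reference for exceedance rates, never for the index math.  A
#: synthetic, user-overridable stand-in for the survey's own choice.
CHINA_BACKGROUND = BackgroundSet(
    provenance="China",
    values={"Cr": 61.0, "Ni": 26.9, "Cu": 22.6, "Zn": 74.2, "As": 11.2, "Pb": 26.0},
)

#: Toxicity response values of the six study metals and the fraction weights.
STUDY_TOXICITY = ToxicityParams(
    tr={"Cr": 2.0, "Ni": 5.0, "Cu": 5.0, "Zn": 1.0, "As": 10.0, "Pb": 5.0},
    theta=(1.6, 1.0, 0.6),
)

STUDY_HAKANSON_CONSTANTS = HakansonConstants()

#: Geoaccumulation-index pollution degrees over boundaries 0, 1, ..., 5.
IGEO_SCHEME = ClassificationScheme(
    kind="igeo",
    labels=(
        "Unpolluted",
        "Lightly polluted",
        "Moderately polluted",
        "Moderately to heavily polluted",
        "Heavily polluted",
        "Heavily to extremely polluted",
        "Extremely polluted",
    ),
    boundaries=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
)

#: Five-class risk labels shared by the Er and RI schemes.
RISK_LABELS: tuple[str, ...] = ("low", "moderate", "considerable", "high", "very high")
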