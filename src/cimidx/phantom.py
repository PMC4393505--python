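"""Synthetic MLO mammogram phantoms with ground truth, and synthetic labeled
transaction cohorts with planted rules.

The phantom emulates the structure the image pipeline assumes: a breast
profile against the left edge (canonical left orientation, chest wall at
column 0), a brighter pectoral-muscle wedge anchored at the top-left corner,
optional lesion discs with one of three margin profiles, a smooth
multiplicative bias field, and additive Gaussian noise.  Truth masks are the
analytic shapes before bias and noise.  No claim of clinical realism is made;
the geometry exists to exercise and score every downstream stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

MARGIN_TYPES = ("circumscribed", "indistinct", "spiculated")

#: diagnosis keywords implied by each lesion margin (morphology + histology + BI-RADS)
MARGIN_KEYWORDS: dict[str, frozenset[str]] = {
    "circumscribed": frozenset({"Circum", "Benign", "BI-RADS 2"}),
    "indistinct": frozenset({"Indist", "Malignant", "BI-RADS 4"}),
    "spiculated": frozenset({"Spicul", "Malignant", "BI-RADS 5"}),
}
NORMAL_KEYWORDS = frozenset({"Normal", "BI-RADS 1"})

# fraction of the breast's horizontal semi-axis where the pectoral boundary
# meets the top edge of the image
_PECTORAL_TOP_FRACTION = 0.45


class PhantomSpecError(ValueError):
    """Raised when a phantom or cohort spec violates its invariants."""


@dataclass(frozen=True)
class Lesion:
    center: tuple[int, int]          # (row, col)
    radius: float                    # pixels
    contrast: float                  # gray-level delta added inside the disc
    margin: str = "circumscribed"    # one of MARGIN_TYPES


@dataclass(frozen=True)
class PhantomSpec:
    width: int = 256
    height: int = 256
    breast_profile: tuple[float, float] = (230.0, 150.0)  # (vertical, horizontal) semi-axes
    pectoral_angle: float = 30.0       # degrees from vertical
    pectoral_intensity: float = 220.0
    breast_intensity: float = 170.0
    background_intensity: float = 5.0
    lesions: tuple[Lesion, ...] = ()
    bias_amplitude: float = 0.0        # gray levels
    noise_sigma: float = 0.0           # gray levels
    seed: int = 0

    def validate(self) -> None:
        if self.width < 64 or self.height < 64:
            raise PhantomSpecError("width/height: must be at least 64 pixels")
        for name in ("pectoral_intensity", "breast_intensity", "background_intensity"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise PhantomSpecError(f"{name}: {v} outside [0, 255]")
        a, b = self.breast_profile
        if a <= 0 or b <= 0:
            raise PhantomSpecError("breast_profile: semi-axes must be positive")
        if not (5.0 <= self.pectoral_angle <= 80.0):
            raise PhantomSpecError("pectoral_angle: must lie in [5, 80] degrees from vertical")
        if self.bias_amplitude < 0:
            raise PhantomSpecError("bias_amplitude: must be nonnegative")
        if self.noise_sigma < 0:
            raise PhantomSpecError("noise_sigma: must be nonnegative")
        for k, les in enumerate(self.lesions):
            if les.margin not in MARGIN_TYPES:
                raise PhantomSpecError(f"lesions[{k}].margin: {les.margin!r} not in {MARGIN_TYPES}")
            if les.radius <= 0:
                raise PhantomSpecError(f"lesions[{k}].radius: must be positive")
            r, c = les.center
            # the whole disc must lie inside the breast profile
            if ((r + les.radius) / a) ** 2 + ((c + les.radius) / b) ** 2 > 1.0:
                raise PhantomSpecError(f"lesions[{k}]: disc extends outside the breast profile")
            if not (0 <= les.contrast + self.breast_intensity <= 255):
                raise PhantomSpecError(f"lesions[{k}].contrast: pushes intensity outside [0, 255]")


@dataclass
class PhantomTruth:
    breast_mask: np.ndarray
    pectoral_mask: np.ndarray
    lesion_masks: list[np.ndarray]
    keywords: frozenset[str]

    def check_invariants(self) -> None:
        assert not np.any(self.pectoral_mask & ~self.breast_mask), "pectoral outside breast"
        for m in self.lesion_masks:
            assert not np.any(m & ~self.breast_mask), "lesion outside breast"
            assert not np.any(m & self.pectoral_mask), "lesion overlaps pectoral"


def pectoral_geometry(spec: PhantomSpec) -> tuple[float, float]:
    """Analytic pectoral boundary: returns (c_top, r_left).

    The boundary is the straight line from (row 0, col c_top) to
    (row r_left, col 0); pixels left of it form the wedge.
    """
    c_top = _PECTORAL_TOP_FRACTION * spec.breast_profile[1]
    r_left = c_top / math.tan(math.radians(spec.pectoral_angle))
    return c_top, r_left


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Render a phantom mammogram and its analytic ground truth.

    Deterministic for a fixed seed; the image is the piecewise-constant
    anatomy times a smooth bias field plus Gaussian noise, clipped to
    [0, 255] and rounded to uint8.
    """
    spec.validate()
    h, w = spec.height, spec.width
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    a, b = spec.breast_profile

    breast = (rr / a) ** 2 + (cc / b) ** 2 <= 1.0

    c_top, _ = pectoral_geometry(spec)
    tan_t = math.tan(math.radians(spec.pectoral_angle))
    pectoral = breast & (cc < c_top - rr * tan_t)

    img = np.full((h, w), spec.background_intensity, dtype=float)
    img[breast] = spec.breast_intensity
    img[pectoral] = spec.pectoral_intensity

    lesion_masks: list[np.ndarray] = []
    for les in spec.lesions:
        r0, c0 = les.center
        d = np.hypot(rr - r0, cc - c0)
        disc = d <= les.radius
        disc &= ~pectoral
        if les.margin == "circumscribed":
            img[disc] += les.contrast
        elif les.margin == "indistinct":
            profile = les.contrast * np.exp(-2.0 * (d / les.radius) ** 2)
            soft = d <= 1.5 * les.radius
            img[soft & ~pectoral] += profile[soft & ~pectoral]
        else:  # spiculated: disc plus radial spikes
            theta = np.arctan2(rr - r0, cc - c0)
            reach = les.radius * (0.75 + 0.45 * np.cos(8.0 * theta) ** 2)
            spik = (d <= reach) & ~pectoral
            img[spik] += les.contrast
        lesion_masks.append(disc)

    if spec.bias_amplitude > 0:
        u = 2.0 * cc / max(w - 1, 1) - 1.0
        v = 2.0 * rr / max(h - 1, 1) - 1.0
        q = 0.6 * u * v + 0.3 * u * u - 0.3 * v * v  # smooth low-order surface
        q = q / max(np.abs(q).max(), 1e-12)
        img = img * (1.0 + (spec.bias_amplitude / 255.0) * q)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)

    img8 = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = PhantomTruth(breast_mask=breast, pectoral_mask=pectoral,
                         lesion_masks=lesion_masks, keywords=phantom_keywords(spec))
    truth.check_invariants()
    return img8, truth


def phantom_keywords(spec: PhantomSpec) -> frozenset[str]:
    """Diagnosis keywords consistent with the lesion spec."""
    if not spec.lesions:
        return NORMAL_KEYWORDS
    kws: set[str] = set()
    for les in spec.lesions:
        kws |= MARGIN_KEYWORDS[les.margin]
    return frozenset(kws)


# ---------------------------------------------------------------------------
# transaction cohorts with planted rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedRule:
    body: frozenset           # feature items (ints in the synthetic universe)
    head: frozenset[str]      # keyword items
    penetrance: float = 1.0   # probability a transaction carries the full body


@dataclass(frozen=True)
class TransactionCohortSpec:
    n_transactions: int
    item_universe: int
    keyword_universe: frozenset[str]
    planted_rules: tuple[PlantedRule, ...]
    noise_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_transactions <= 0:
            raise PhantomSpecError("n_transactions: must be positive")
        if self.item_universe <= 0:
            raise PhantomSpecError("item_universe: must be positive")
        if not self.planted_rules:
            raise PhantomSpecError("planted_rules: must not be empty")
        if not (0.0 <= self.noise_rate <= 1.0):
            raise PhantomSpecError("noise_rate: must lie in [0, 1]")
        for k, rule in enumerate(self.planted_rules):
            if not (0.0 <= rule.penetrance <= 1.0):
                raise PhantomSpecError(f"planted_rules[{k}].penetrance: must lie in [0, 1]")
            if not all(isinstance(i, (int, np.integer)) and 0 <= i < self.item_universe
                       for i in rule.body):
                raise PhantomSpecError(f"planted_rules[{k}].body: items outside the universe")
            if not rule.head or not rule.head <= self.keyword_universe:
                raise PhantomSpecError(f"planted_rules[{k}].head: must be nonempty keywords "
                                       "from the keyword universe")


def generate_transactions(spec: TransactionCohortSpec) -> list[tuple[frozenset, frozenset]]:
    """Sample labeled transactions: pick a planted rule uniformly, include its
    body with probability penetrance, label with its head, then flip each
    feature item's membership independently at the noise rate."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rules = spec.planted_rules
    out: list[tuple[frozenset, frozenset]] = []
    for _ in range(spec.n_transactions):
        rule = rules[int(rng.integers(len(rules)))]
        items = set(rule.body) if rng.random() < rule.penetrance else set()
        if spec.noise_rate > 0:
            flips = np.nonzero(rng.random(spec.item_universe) < spec.noise_rate)[0]
            items ^= set(int(i) for i in flips)
        out.append((frozenset(items), rule.head))
    return out
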