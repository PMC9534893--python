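"""Synthetic factorial morphology data and rendered leaf images.

The original greenhouse dataset behind this pipeline (two pomegranate
cultivars under drought/salinity stress with foliar GABA at 0--40 mM) is
not publicly deposited, so this module generates stand-in data with a
known ground truth.  Two kinds of artifacts are produced:

* tabular morphology records from a completely randomized factorial
  design (cultivar x GABA dose x stress regime x time point x replicate),
  with five traits per record: crown diameter (CD), plant height (PH),
  leaf length index (LLI), leaf width index (LWI) and leaf area index
  (LAI);
* RGB images of single leaves on a light background, with a pixel-exact
  ground-truth sidecar, used to test the image-morphometry stage.

The generative model for a trait value is multiplicative,

    trait = baseline(cultivar) * growth(day) * penalty(stress, cultivar)
            * gain(GABA dose)  +  correlated Gaussian noise,

which reproduces the qualitative structure reported for this system:
combined drought+salinity is the most damaging regime, 'Atabaki' is more
stress tolerant than 'Rabab', traits increase with GABA dose, and all
trait pairs are positively correlated.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DesignError, ParameterError, RenderError

#: Canonical trait order used everywhere in the package.
TRAITS = ("CD", "PH", "LLI", "LWI", "LAI")

#: Canonical input-factor order (matches the encoded design matrix).
INPUT_COLUMNS = ("cultivar", "stress", "gaba_mM", "day")

#: Column layout of a generated dataset.
DATASET_COLUMNS = INPUT_COLUMNS[:2] + ("gaba_mM", "day", "replicate") + TRAITS


# ---------------------------------------------------------------------------
# experiment design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentDesign:
    """A completely randomized factorial design.

    ``n_records`` equals the product of the level counts times the number
    of replicates.
    """

    cultivars: tuple[str, ...]
    gaba_levels_mM: tuple[float, ...]
    stress_levels: tuple[str, ...]
    timepoints_days: tuple[float, ...]
    replicates: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "cultivars", tuple(self.cultivars))
        object.__setattr__(self, "gaba_levels_mM", tuple(float(g) for g in self.gaba_levels_mM))
        object.__setattr__(self, "stress_levels", tuple(self.stress_levels))
        object.__setattr__(self, "timepoints_days", tuple(float(d) for d in self.timepoints_days))
        for name in ("cultivars", "gaba_levels_mM", "stress_levels", "timepoints_days"):
            levels = getattr(self, name)
            if len(levels) == 0:
                raise DesignError(f"factor '{name}' has no levels")
            if len(set(levels)) != len(levels):
                raise DesignError(f"factor '{name}' has duplicate levels: {levels}")
        if any(g < 0 for g in self.gaba_levels_mM):
            raise DesignError("GABA levels must be non-negative")
        if any(d < 0 for d in self.timepoints_days):
            raise DesignError("time points must be non-negative")
        if int(self.replicates) < 1:
            raise DesignError("replicates must be a positive integer")
        object.__setattr__(self, "replicates", int(self.replicates))

    @property
    def n_records(self) -> int:
        return (
            len(self.cultivars)
            * len(self.gaba_levels_mM)
            * len(self.stress_levels)
            * len(self.timepoints_days)
            * self.replicates
        )


def pomegranate_design(replicates: int = 4) -> ExperimentDesign:
    """The study layout: 2 cultivars x 4 GABA doses x 4 stress regimes
    x 4 time points x 4 replicates = 512 records.

    Day 0 encodes the measurement taken before stress was applied.
    """
    return ExperimentDesign(
        cultivars=("Atabaki", "Rabab"),
        gaba_levels_mM=(0.0, 10.0, 20.0, 40.0),
        stress_levels=("control", "drought", "salt", "combined"),
        timepoints_days=(0.0, 14.0, 30.0, 45.0),
        replicates=replicates,
    )


def build_design(design: ExperimentDesign) -> pd.DataFrame:
    """Enumerate every factor combination, replicated.

    Returns a data frame with columns ``cultivar, stress, gaba_mM, day,
    replicate`` and exactly ``design.n_records`` rows; every combination
    appears exactly ``design.replicates`` times.
    """
    rows = [
        (c, s, g, d, r)
        for c, g, s, d in itertools.product(
            design.cultivars,
            design.gaba_levels_mM,
            design.stress_levels,
            design.timepoints_days,
        )
        for r in range(1, design.replicates + 1)
    ]
    frame = pd.DataFrame(rows, columns=["cultivar", "stress", "gaba_mM", "day", "replicate"])
    assert len(frame) == design.n_records
    return frame


# ---------------------------------------------------------------------------
# generator parameters and the trait mean model
# ---------------------------------------------------------------------------

def _default_correlation() -> np.ndarray:
    # replicate-level (noise) correlation between traits, order CD PH LLI LWI LAI;
    # leaf traits co-vary more tightly than whole-plant traits
    return np.array(
        [
            [1.0, 0.5, 0.5, 0.5, 0.5],
            [0.5, 1.0, 0.5, 0.5, 0.5],
            [0.5, 0.5, 1.0, 0.7, 0.7],
            [0.5, 0.5, 0.7, 1.0, 0.8],
            [0.5, 0.5, 0.7, 0.8, 1.0],
        ]
    )


@dataclass
class GeneratorParams:
    """Parameters of the multiplicative trait model.

    ``baselines`` gives the day-0, unstressed, GABA-free trait means (cm)
    per cultivar.  ``stress_penalty`` maps each regime to a multiplier in
    (0, 1]; combined stress must penalize more than either single stress
    and 'control' must map to 1.  ``susceptibility`` scales how strongly
    a cultivar expresses the stress penalty (the tolerant cultivar has
    the smaller value).  The GABA dose response is saturating,
    ``1 + gmax * dose / (dose + half_sat)``, unless ``gaba_optimum_mM``
    is set, in which case a smooth unimodal response
    ``1 + gmax * (d/opt) * exp(1 - d/opt)`` peaking exactly at the
    optimum is used.  ``trait_correlation`` is the replicate-level noise
    correlation; total trait correlations in a generated dataset are
    higher because treatments move all traits together.
    """

    baselines: Mapping[str, Mapping[str, float]]
    stress_penalty: Mapping[str, float]
    susceptibility: Mapping[str, float]
    gaba_max_gain: float = 0.25
    gaba_half_sat_mM: float = 8.0
    gaba_optimum_mM: float | None = None
    growth_rate: Mapping[str, float] = field(
        default_factory=lambda: {t: 0.008 for t in TRAITS}
    )
    trait_correlation: np.ndarray = field(default_factory=_default_correlation)
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(zip(TRAITS, (2.0, 16.0, 0.65, 0.20, 1.5)))
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.trait_correlation = np.asarray(self.trait_correlation, dtype=float)
        corr = self.trait_correlation
        if corr.shape != (len(TRAITS), len(TRAITS)):
            raise ParameterError("trait_correlation must be 5x5")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ParameterError("trait_correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ParameterError("trait_correlation must have a unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ParameterError("trait_correlation must be positive semi-definite")
        for label, p in self.stress_penalty.items():
            if not 0.0 < p <= 1.0:
                raise ParameterError(f"stress penalty for '{label}' must be in (0, 1]")
        sp = self.stress_penalty
        if "control" in sp and sp["control"] != 1.0:
            raise ParameterError("the control regime must have penalty 1.0")
        singles = [sp[k] for k in ("drought", "salt") if k in sp]
        if "combined" in sp and singles and not all(sp["combined"] < s for s in singles):
            raise ParameterError(
                "combined-stress penalty must be below each single-stress penalty"
            )
        if singles and not all(s < 1.0 for s in singles):
            raise ParameterError("single-stress penalties must be below 1 (control)")
        for label, s in self.susceptibility.items():
            if not 0.0 < s <= 1.5:
                raise ParameterError(f"susceptibility for '{label}' must be in (0, 1.5]")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ParameterError("noise sd must be non-negative")
        if self.gaba_max_gain < 0:
            raise ParameterError("gaba_max_gain must be non-negative")
        if self.gaba_half_sat_mM <= 0:
            raise ParameterError("gaba_half_sat_mM must be positive")
        if self.gaba_optimum_mM is not None and self.gaba_optimum_mM <= 0:
            raise ParameterError("gaba_optimum_mM must be positive when set")


def default_generator_params(seed: int = 0) -> GeneratorParams:
    """Illustrative defaults whose trait ranges bracket the optima the
    pipeline typically reports (CD ~ 18 cm, PH ~ 150 cm, LLI ~ 5.7 cm,
    LWI ~ 1.8 cm, LAI ~ 14); they are not fitted to real data."""
    atabaki = {"CD": 13.5, "PH": 110.0, "LLI": 4.2, "LWI": 1.35, "LAI": 10.0}
    rabab = {t: 0.88 * v for t, v in atabaki.items()}
    return GeneratorParams(
        baselines={"Atabaki": atabaki, "Rabab": rabab},
        stress_penalty={"control": 1.0, "drought": 0.85, "salt": 0.80, "combined": 0.62},
        susceptibility={"Atabaki": 0.7, "Rabab": 1.0},
        seed=seed,
    )


def gaba_gain(dose_mM, params: GeneratorParams):
    """Relative growth gain from a foliar GABA dose (gain(0) = 1)."""
    d = np.asarray(dose_mM, dtype=float)
    if params.gaba_optimum_mM is None:
        out = 1.0 + params.gaba_max_gain * d / (d + params.gaba_half_sat_mM)
    else:
        g = d / params.gaba_optimum_mM
        out = 1.0 + params.gaba_max_gain * g * np.exp(1.0 - g)
    return out if out.ndim else float(out)


def expected_traits(
    params: GeneratorParams,
    cultivar,
    stress,
    gaba_mM,
    day,
) -> np.ndarray:
    """Noise-free trait means, shape (n, 5) in the :data:`TRAITS` order.

    Accepts scalars or equal-length sequences for all four factors.
    """
    cultivar = np.atleast_1d(np.asarray(cultivar, dtype=object))
    stress = np.atleast_1d(np.asarray(stress, dtype=object))
    gaba = np.atleast_1d(np.asarray(gaba_mM, dtype=float))
    day = np.atleast_1d(np.asarray(day, dtype=float))
    n = max(len(cultivar), len(stress), len(gaba), len(day))
    cultivar, stress, gaba, day = (
        np.broadcast_to(a, (n,)) for a in (cultivar, stress, gaba, day)
    )

    try:
        base = np.array(
            [[params.baselines[c][t] for t in TRAITS] for c in cultivar]
        )
        penalty = np.array([params.stress_penalty[s] for s in stress])
        susc = np.array([params.susceptibility[c] for c in cultivar])
    except KeyError as exc:  # pragma: no cover - message clarity only
        raise ParameterError(f"level {exc} missing from generator parameters") from exc

    penalty_eff = 1.0 - (1.0 - penalty) * susc
    gain = gaba_gain(gaba, params)
    rates = np.array([params.growth_rate[t] for t in TRAITS])
    growth = 1.0 + np.outer(day, rates)
    return base * growth * (penalty_eff * gain)[:, None]


def generate_morphology(design: ExperimentDesign, params: GeneratorParams) -> pd.DataFrame:
    """Generate one dataset from the design: the factor table plus the
    five traits, with correlated Gaussian noise on the trait scale.

    Deterministic given ``params.seed``.  Trait values are floored at
    0.01 cm so the all-positive invariant holds even for noisy draws.
    """
    frame = build_design(design)
    mu = expected_traits(
        params,
        frame["cultivar"].to_numpy(),
        frame["stress"].to_numpy(),
        frame["gaba_mM"].to_numpy(),
        frame["day"].to_numpy(),
    )
    sds = np.array([params.noise_sd[t] for t in TRAITS])
    if np.any(sds > 0):
        cov = params.trait_correlation * np.outer(sds, sds)
        evals, evecs = np.linalg.eigh(cov)
        root = evecs * np.sqrt(np.clip(evals, 0.0, None))
        rng = np.random.default_rng(params.seed)
        noise = rng.standard_normal((len(frame), len(TRAITS))) @ root.T
        mu = mu + noise
    values = np.maximum(mu, 0.01)
    for j, t in enumerate(TRAITS):
        frame[t] = values[:, j]
    return frame


# ---------------------------------------------------------------------------
# leaf image rendering
# ---------------------------------------------------------------------------

@dataclass
class LeafShapeSpec:
    """A single synthetic leaf: a superellipse lamina with an explicit
    petiole stub, rasterized at ``px_per_cm``.

    ``exponent`` = 2 gives an ellipse.  ``speckle_rate`` flips background
    pixels to dark specks; ``hole_rate`` flips lamina pixels to the
    background colour (holes).  Noise affects the rendered image only;
    the ground truth describes the clean shape.
    """

    length_cm: float
    width_cm: float
    px_per_cm: float = 20.0
    exponent: float = 2.0
    petiole_frac: float = 0.12
    petiole_px: int = 3
    speckle_rate: float = 0.0
    hole_rate: float = 0.0
    color_jitter_sd: float = 0.0
    margin_px: int = 12
    canvas_px: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.length_cm >= self.width_cm > 0:
            raise ParameterError("need length_cm >= width_cm > 0")
        if self.px_per_cm <= 0:
            raise ParameterError("px_per_cm must be positive")
        if self.exponent <= 0 or self.petiole_frac < 0:
            raise ParameterError("exponent must be > 0 and petiole_frac >= 0")
        if not (0 <= self.speckle_rate < 1 and 0 <= self.hole_rate < 1):
            raise ParameterError("noise rates must be in [0, 1)")


_LEAF_RGB = np.array([45, 95, 35], dtype=float)
_BG_RGB = np.array([246, 246, 244], dtype=float)
_SPECK_RGB = np.array([35, 35, 35], dtype=float)


def render_leaf_image(spec: LeafShapeSpec):
    """Rasterize the leaf and return ``(image, ground_truth)``.

    ``image`` is an (H, W, 3) uint8 array: dark leaf on a near-white
    background.  ``ground_truth`` is a dict with the clean boolean
    ``mask``, the continuous tip / lamina-base (petiole intersection) /
    petiole-end coordinates as (row, col), and ``length_px`` (tip to
    petiole intersection), ``width_px`` (maximal lamina width) and
    ``area_px`` (foreground pixel count of the clean mask).
    """
    a = spec.length_cm * spec.px_per_cm / 2.0  # semi-major, columns
    b = spec.width_cm * spec.px_per_cm / 2.0   # semi-minor, rows
    petiole_len = spec.petiole_frac * spec.length_cm * spec.px_per_cm

    width_needed = int(math.ceil(2 * a + petiole_len)) + 2 * spec.margin_px
    height_needed = int(math.ceil(2 * b)) + 2 * spec.margin_px
    if spec.canvas_px is None:
        height, width = height_needed, width_needed
    else:
        height, width = spec.canvas_px
        if height < height_needed or width < width_needed:
            raise RenderError(
                f"leaf needs a {height_needed}x{width_needed} canvas, "
                f"got {height}x{width}"
            )

    yc = height / 2.0
    xc = spec.margin_px + petiole_len + a
    rows = np.arange(height)[:, None]
    cols = np.arange(width)[None, :]
    lamina = (
        np.abs((cols - xc) / a) ** spec.exponent
        + np.abs((rows - yc) / b) ** spec.exponent
    ) <= 1.0
    petiole = (
        (np.abs(rows - yc) <= spec.petiole_px / 2.0)
        & (cols >= xc - a - petiole_len)
        & (cols <= xc - a)
    )
    mask = lamina | petiole

    rng = np.random.default_rng(spec.seed)
    image = np.empty((height, width, 3), dtype=float)
    image[~mask] = _BG_RGB
    image[mask] = _LEAF_RGB
    if spec.color_jitter_sd > 0:  # sensor-like shot noise
        image += rng.normal(0.0, spec.color_jitter_sd, size=image.shape)

    if spec.speckle_rate > 0:
        speck = (~mask) & (rng.random((height, width)) < spec.speckle_rate)
        image[speck] = _SPECK_RGB
    if spec.hole_rate > 0:
        holes = lamina & (rng.random((height, width)) < spec.hole_rate)
        image[holes] = _BG_RGB

    ground_truth = {
        "mask": mask,
        "tip_rc": (yc, xc + a),
        "base_rc": (yc, xc - a),
        "petiole_end_rc": (yc, xc - a - petiole_len),
        "length_px": 2.0 * a,
        "width_px": 2.0 * b,
        "area_px": int(mask.sum()),
        "px_per_cm": spec.px_per_cm,
    }
    return np.clip(image, 0, 255).astype(np.uint8), ground_truth
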