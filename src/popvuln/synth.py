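"""Synthetic landscapes, occurrences, and plant censuses.

The real census coordinates for the study species are withheld, so every
downstream stage is exercised on generated data that carries the same
statistical structure the analysis assumes:

* spatially autocorrelated, standardized climate layers (Gaussian random
  fields, optionally with a latitudinal gradient);
* a narrow Gaussian climatic niche that clusters occurrences in the top
  suitability cells;
* future scenarios that shift the climate directionally (warming/drying)
  plus scenario-specific noise;
* per-population stem-length distributions whose mean falls — and whose
  young-plant fraction rises — with a planted vulnerability ``v_k``.

The planted vulnerability is realized *geographically*: populations are
spread along the climatic gradient so that future suitability loss differs
among them.  The coupling between demography and vulnerability therefore
runs through space, and recovering it requires the full suitability-model
plus vulnerability-index machinery, not a lookup of the labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .rasters import ClimateStack, GridGeometry, ScenarioSet

# Stem length (cm) at or below which a plant is classed as young.
YOUNG_THRESHOLD_CM = 30.0

#: Plants-per-population counts of the thirteen censused populations
#: (n = 1615 in total), used as the default census sizes.
DEFAULT_PLANTS_PER_POPULATION = (11, 209, 109, 4, 77, 298, 22, 283, 181, 89, 251, 33, 48)

DEFAULT_LAYER_NAMES = ("bio03", "bio07", "bio15", "bio19")

GCM_LABELS = ("gcm-a", "gcm-b", "gcm-c", "gcm-d", "gcm-e")
SSP_LABELS = ("SSP1-RCP2.6", "SSP5-RCP8.5")


@dataclass
class SyntheticTruth:
    """Generative ground truth recorded alongside every synthetic dataset.

    ``beta_len`` is the change in mean stem length (cm) per unit of planted
    vulnerability (negative: more vulnerable populations have shorter
    stems); ``beta_young`` the change in the logit of the young-plant
    fraction (positive).  ``v_range`` bounds the realized per-population
    vulnerability ``v_k``, which is assigned from each population's
    position along the climatic gradient.
    """

    niche_center: dict[str, float]
    niche_width: dict[str, float]
    expected_shift: dict[str, float] = field(default_factory=dict)
    mu0_cm: float = 130.0
    beta_len: float = -100.0
    alpha_young: float = -3.0
    beta_young: float = 2.8
    v_range: tuple[float, float] = (0.5, 1.0)
    p_fruiting_adult: float = 0.37
    p_flowering_adult: float = 0.2
    p_flowering_young: float = 0.03
    seed: int | None = None
    v_k: list[float] = field(default_factory=list)  # realized per population

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        d["v_range"] = tuple(d["v_range"])
        return cls(**d)


@dataclass
class SyntheticDataset:
    """Everything one replicate of the generator produces."""

    scenarios: ScenarioSet
    occurrences: np.ndarray          # (n_plants, 2) x,y of every plant
    census: pd.DataFrame             # plant_id, population, x, y, stem_length_cm, status
    truth: SyntheticTruth


def _gaussian_field(n_rows: int, n_cols: int, autocorr_range: float, rng: np.random.Generator) -> np.ndarray:
    """Smoothed white noise, standardized to mean 0 / sd 1 over cells."""
    white = rng.standard_normal((n_rows, n_cols))
    smooth = ndimage.gaussian_filter(white, sigma=autocorr_range, mode="reflect")
    smooth -= smooth.mean()
    sd = smooth.std(ddof=0)
    if sd == 0:  # pragma: no cover - only possible on degenerate input
        raise ValueError("random field degenerated to a constant")
    return smooth / sd


def generate_climate_stack(
    n_rows: int,
    n_cols: int,
    layer_names: Sequence[str] = DEFAULT_LAYER_NAMES,
    autocorr_range: float = 4.0,
    seed: int = 0,
    gradient: Mapping[str, float] | None = None,
    cell_size: float = 1000.0,
    x0: float = 0.0,
    y0: float = 0.0,
) -> ClimateStack:
    """Generate a stack of standardized, spatially autocorrelated layers.

    Each layer is white noise convolved with an isotropic Gaussian kernel of
    scale ``autocorr_range`` (in cells), then standardized to mean 0 and
    sd 1 over all cells.  ``gradient`` optionally adds a south-to-north
    linear trend of the given amplitude (in sd units, before the final
    standardization) to named layers, giving the landscape a latitudinal
    climate axis.  Deterministic for a given seed.
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError("grid must be at least 8 x 8 cells")
    if autocorr_range < 1:
        raise ValueError("autocorr_range must be >= 1 cell")
    gradient = dict(gradient or {})
    unknown = set(gradient) - set(layer_names)
    if unknown:
        raise KeyError(f"gradient keys not in layer_names: {sorted(unknown)}")
    geo = GridGeometry(x0=x0, y0=y0, cell_size=cell_size, n_rows=n_rows, n_cols=n_cols)
    rng = np.random.default_rng(seed)
    rows = np.linspace(-1.0, 1.0, n_rows)[:, None] * np.ones((1, n_cols))
    layers = {}
    for name in layer_names:
        f = _gaussian_field(n_rows, n_cols, autocorr_range, rng)
        amp = gradient.get(name, 0.0)
        if amp:
            f = f + amp * rows
            f -= f.mean()
            f /= f.std(ddof=0)
        layers[name] = f
    return ClimateStack(layers, geo)


def generate_future_stack(
    present: ClimateStack,
    shift: Mapping[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ClimateStack:
    """Shift present layers additively (sd units) and add white noise."""
    unknown = set(shift) - set(present.layer_names)
    if unknown:
        raise KeyError(f"shift names a layer not in the stack: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    layers = {}
    for name in present.layer_names:
        arr = present[name] + shift.get(name, 0.0)
        if noise_sd > 0:
            arr = arr + noise_sd * rng.standard_normal(arr.shape)
        layers[name] = arr
    return ClimateStack(layers, present.geometry, validate=False)


def niche_suitability(stack: ClimateStack, truth: SyntheticTruth) -> np.ndarray:
    """True suitability surface: product of per-predictor Gaussian kernels."""
    p = np.ones((stack.geometry.n_rows, stack.geometry.n_cols))
    for name, c in truth.niche_center.items():
        w = truth.niche_width[name]
        p *= np.exp(-((stack[name] - c) ** 2) / (2.0 * w**2))
    return p


def gamma_from_mean_and_young_fraction(
    mean_cm: float, young_fraction: float, threshold_cm: float = YOUNG_THRESHOLD_CM
) -> tuple[float, float]:
    """Solve gamma shape/scale so that E[X] = mean and P(X <= t) = fraction.

    For a fixed mean the CDF at the threshold is monotone in the shape
    parameter, so a bracketing root-finder suffices.  Targets outside the
    range attainable for shapes in [0.05, 200] are clamped to the nearest
    attainable value.
    """
    if mean_cm <= 0:
        raise ValueError("mean stem length must be positive")
    if not 0 < young_fraction < 1:
        raise ValueError("young fraction must be in (0, 1)")

    def cdf_at(shape: float) -> float:
        return stats.gamma.cdf(threshold_cm, shape, scale=mean_cm / shape)

    lo, hi = 0.05, 200.0
    f_lo, f_hi = cdf_at(lo) - young_fraction, cdf_at(hi) - young_fraction
    if f_lo * f_hi > 0:
        shape = lo if abs(f_lo) < abs(f_hi) else hi
    else:
        shape = optimize.brentq(lambda a: cdf_at(a) - young_fraction, lo, hi)
    return shape, mean_cm / shape


def generate_species_occurrences(
    stack: ClimateStack,
    truth: SyntheticTruth,
    n_populations: int = 13,
    plants_per_population: Sequence[int] = DEFAULT_PLANTS_PER_POPULATION,
    seed: int = 0,
    scatter_sd_cells: float = 0.03,
) -> SyntheticDataset:
    """Place populations in the climatic niche and draw their censuses.

    Population centers are sampled from cells in the top suitability decile,
    spread along the gradient layer (the first niche predictor) by picking
    evenly spaced quantiles of that layer's value among eligible cells.  The
    planted vulnerability ``v_k`` is realized geographically: under the
    truth's expected climate shift each center cell has a true future
    suitability (the Gaussian niche kernel evaluated at its shifted
    climate), and ``v_k`` maps the *negated* future suitabilities into
    ``truth.v_range`` — populations whose location the shift pushes
    furthest out of the niche get the largest ``v_k``.  Stem lengths are
    gamma with mean ``mu0 + beta_len * v_k`` and
    young fraction ``logit^-1(alpha + beta_young * v_k)``; reproductive
    status is assigned to adults with the truth's probabilities and to young
    plants (<= 30 cm) only as rare flowering.
    """
    if n_populations < 2:
        raise ValueError("need at least two populations")
    plants_per_population = list(plants_per_population)
    if len(plants_per_population) != n_populations:
        raise ValueError(
            f"plants_per_population has {len(plants_per_population)} entries "
            f"for {n_populations} populations"
        )
    if min(plants_per_population) < 1:
        raise ValueError("every population needs at least one plant")

    rng = np.random.default_rng(seed)
    geo = stack.geometry
    suit = niche_suitability(stack, truth)
    cutoff = np.quantile(suit, 0.9)
    rows, cols = np.where(suit >= cutoff)
    gradient_layer = next(iter(truth.niche_center))
    gvals = stack[gradient_layer][rows, cols]
    order = np.argsort(gvals)
    # evenly spaced quantile positions along the gradient within the niche
    q = (np.arange(n_populations) + 0.5) / n_populations
    picks = order[np.clip((q * len(order)).astype(int), 0, len(order) - 1)]
    center_cells = np.column_stack([rows[picks], cols[picks]])

    # planted vulnerability: true future suitability at each center cell,
    # negated and ranged — the truth-level analog of the vulnerability index
    deficit = np.zeros(n_populations)
    for name, c in truth.niche_center.items():
        w = truth.niche_width[name]
        x = stack[name][center_cells[:, 0], center_cells[:, 1]]
        x_fut = x + truth.expected_shift.get(name, 0.0)
        deficit += (x_fut - c) ** 2 / (2.0 * w**2)
    s_fut_true = np.exp(-deficit)
    v_lo, v_hi = truth.v_range
    span = s_fut_true.max() - s_fut_true.min()
    rel = (s_fut_true.max() - s_fut_true) / span if span > 0 else np.zeros_like(deficit)
    v_k = v_lo + (v_hi - v_lo) * rel
    truth.v_k = [float(v) for v in v_k]
    truth.seed = int(seed)

    records = []
    all_xy = []
    plant_id = 0
    h = geo.cell_size
    for k in range(n_populations):
        n_k = plants_per_population[k]
        cx, cy = geo.cell_center(*center_cells[k])
        mu_k = truth.mu0_cm + truth.beta_len * v_k[k]
        mu_k = max(mu_k, 5.0)
        pi_k = 1.0 / (1.0 + np.exp(-(truth.alpha_young + truth.beta_young * v_k[k])))
        shape, scale = gamma_from_mean_and_young_fraction(mu_k, pi_k)
        lengths = rng.gamma(shape, scale, size=n_k)
        lengths = np.maximum(lengths, 0.1)  # strictly positive
        # scatter plants around the center; clip into the grid interior
        xs = np.clip(cx + rng.normal(0, scatter_sd_cells * h, n_k), geo.x0, np.nextafter(geo.x_max, geo.x0))
        ys = np.clip(cy + rng.normal(0, scatter_sd_cells * h, n_k), geo.y0, np.nextafter(geo.y_max, geo.y0))
        for x, y, length in zip(xs, ys, lengths):
            if length > YOUNG_THRESHOLD_CM:
                u = rng.uniform()
                if u < truth.p_fruiting_adult:
                    status = "fruiting"
                elif u < truth.p_fruiting_adult + truth.p_flowering_adult:
                    status = "flowering"
                else:
                    status = "non_reproductive"
            else:
                status = "flowering" if rng.uniform() < truth.p_flowering_young else "non_reproductive"
            records.append(
                (f"p{plant_id:05d}", f"pop{k:02d}", float(x), float(y), float(length), status)
            )
            all_xy.append((x, y))
            plant_id += 1

    census = pd.DataFrame(
        records, columns=["plant_id", "population", "x", "y", "stem_length_cm", "status"]
    )
    dataset = SyntheticDataset(
        scenarios=ScenarioSet(present=stack),
        occurrences=np.asarray(all_xy, dtype=float),
        census=census,
        truth=truth,
    )
    return dataset


def default_truth(
    stack: ClimateStack,
    gradient_layer: str = "bio03",
    expected_shift: float = -0.475,
) -> SyntheticTruth:
    """Default narrow niche at the warm edge of the gradient layer.

    The niche center sits at the 97th percentile of the gradient layer —
    an edge niche: suitability increases monotonically toward the
    northern, high-gradient end of the landscape, the regime where a
    trailing-edge species persists at the margin of its climate space,
    and one a monotone suitability learner can represent.  The gradient
    layer carries a narrow kernel (width 0.5 sd) and is the axis future
    scenarios shift; the remaining layers enter with wide kernels
    (2.5 sd) and contribute only mild non-gradient structure.
    ``expected_shift`` (the across-pathway mean of the default scenario
    shifts) defines the true future suitability used to realize the
    planted per-population vulnerability.
    """
    center = {gradient_layer: float(np.quantile(stack[gradient_layer], 0.97))}
    width = {gradient_layer: 0.5}
    for name in stack.layer_names:
        if name != gradient_layer:
            center[name] = 0.0
            width[name] = 2.5
    return SyntheticTruth(
        niche_center=center,
        niche_width=width,
        expected_shift={gradient_layer: expected_shift},
    )


def generate_scenario_set(
    stack: ClimateStack,
    gradient_layer: str = "bio03",
    shift_ssp126: float = -0.35,
    shift_ssp585: float = -0.6,
    gcm_jitter_sd: float = 0.08,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> ScenarioSet:
    """Build the 5 GCM x 2 pathway future set around a present stack.

    Warming/drying is emulated as a negative shift of the gradient layer
    (conditions everywhere move away from the niche, which sits at the
    high-gradient edge); the high-emissions pathway shifts further.  Each
    GCM perturbs the pathway shift by a deterministic jitter and adds white
    noise, so the ten futures disagree the way an ensemble of circulation
    models does.
    """
    rng = np.random.default_rng(seed)
    futures = []
    for g, gcm in enumerate(GCM_LABELS):
        jit = rng.normal(0.0, gcm_jitter_sd)
        for ssp, base in ((SSP_LABELS[0], shift_ssp126), (SSP_LABELS[1], shift_ssp585)):
            fut = generate_future_stack(
                stack,
                shift={gradient_layer: base + jit},
                noise_sd=noise_sd,
                seed=int(rng.integers(2**31 - 1)),
            )
            futures.append((gcm, ssp, fut))
    return ScenarioSet(present=stack, futures=futures)


def generate_dataset(
    n_rows: int = 32,
    n_cols: int = 32,
    layer_names: Sequence[str] = DEFAULT_LAYER_NAMES,
    autocorr_range: float = 4.0,
    gradient_layer: str = "bio03",
    gradient_amplitude: float = 2.0,
    n_populations: int = 13,
    plants_per_population: Sequence[int] = DEFAULT_PLANTS_PER_POPULATION,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
) -> SyntheticDataset:
    """One-call generator: present stack, 10 futures, occurrences, census."""
    ss = np.random.SeedSequence(seed)
    s_stack, s_occ, s_fut = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3))
    stack = generate_climate_stack(
        n_rows, n_cols, layer_names, autocorr_range, seed=s_stack,
        gradient={gradient_layer: gradient_amplitude},
    )
    if truth is None:
        truth = default_truth(stack, gradient_layer)
    data = generate_species_occurrences(
        stack, truth, n_populations, plants_per_population, seed=s_occ
    )
    data.scenarios = generate_scenario_set(stack, gradient_layer, seed=s_fut)
    return data
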