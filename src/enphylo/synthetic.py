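"""Virtual-species simulator with known ground truth.

Everything downstream (niche fitting, imputation, ensembles, projection,
diversity change) is exercised on landscapes, phylogenies and occurrence
samples produced here, so recovery against truth is always measurable.

The generator emulates:

* multi-layer environmental rasters — smooth climate-like gradients with
  spatially autocorrelated noise, plus land-cover "distance from category"
  layers built as Euclidean distance transforms from seeded patches;
* a clade whose per-layer niche optima evolved by Brownian motion on a
  simulated birth–death tree (so climatic preferences carry phylogenetic
  signal);
* per-species occurrence counts spanning everything from 2 cells (the
  rare-species extension target) to data-rich species;
* future scenario stacks: additive climate shifts with per-GCM jitter,
  land-cover patch relocation, and their combination, at a mild (half
  shift) and a severe (full shift) intensity.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InputError
from .geodata import Cell, EnvStack, OccurrenceSet

MILD = "mild"
SEVERE = "severe"
SCENARIO_CURRENT = "current"
SCENARIO_CLIMATE = "climate"
SCENARIO_LULC = "lulc"
SCENARIO_BOTH = "both"


@dataclass
class LandscapeInfo:
    """Bookkeeping for a simulated landscape (needed to build futures)."""

    climate_layers: list[str]
    lulc_layers: list[str]
    lulc_patches: dict[str, list[Cell]]


@dataclass
class VirtualTruth:
    """Ground truth of a simulated clade."""

    tree: dendropy.Tree
    niche_optima: pd.DataFrame          # species x layer, z-score units
    niche_breadths: pd.DataFrame | None = None
    true_suitability: dict[str, np.ndarray] = field(default_factory=dict)
    occurrence_counts: dict[str, int] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return list(self.niche_optima.index)


@dataclass
class ScenarioSet:
    """Named scenario stacks sharing the grid of ``current``.

    Keys are ``(scenario, gcm, ssp)`` tuples where ``scenario`` is one of
    ``current | climate | lulc | both``; ``gcm`` is None for ``current`` and
    ``lulc`` (climate held constant there), ``ssp`` is None for ``current``.
    """

    stacks: dict[tuple[str, str | None, str | None], EnvStack]

    @property
    def current(self) -> EnvStack:
        return self.stacks[(SCENARIO_CURRENT, None, None)]

    def keys(self):
        return self.stacks.keys()

    def __getitem__(self, key):
        return self.stacks[key]


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def _smooth_noise(rng, shape, sigma_cells: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if sigma_cells <= 0:
        return noise
    sm = ndimage.gaussian_filter(noise, sigma=sigma_cells, mode="reflect")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def simulate_landscape(
    nrows: int,
    ncols: int,
    n_climate_layers: int = 5,
    n_lulc_layers: int = 3,
    spatial_corr_range: float = 5.0,
    cell_size: float = 1.0,
    seed: int = 0,
    n_patches: int = 3,
    nodata_fraction: float = 0.0,
) -> tuple[EnvStack, LandscapeInfo]:
    """Simulate an aligned environmental stack.

    Climate layers are a random linear gradient plus Gaussian-kernel
    smoothed white noise (kernel width ``spatial_corr_range`` km; 0 gives
    pure white noise).  LULC layers are Euclidean distances (km) from
    ``n_patches`` randomly seeded category patches.  Deterministic under
    ``seed``.
    """
    if nrows < 10 or ncols < 10:
        raise InputError("landscape must be at least 10 x 10")
    rng = np.random.default_rng(seed)
    yy, xx = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    xx = xx / max(ncols - 1, 1)
    yy = yy / max(nrows - 1, 1)
    layers, names = [], []
    for i in range(n_climate_layers):
        theta = rng.uniform(0, 2 * np.pi)
        gradient = np.cos(theta) * xx + np.sin(theta) * yy
        noise = _smooth_noise(rng, (nrows, ncols), spatial_corr_range / cell_size)
        amp = rng.uniform(0.5, 2.0)
        offset = rng.uniform(-5, 5)
        layers.append(offset + amp * (2.0 * gradient + noise))
        names.append(f"clim{i + 1}")
    info_patches: dict[str, list[Cell]] = {}
    for i in range(n_lulc_layers):
        name = f"lulcdist{i + 1}"
        patches = [
            (int(rng.integers(nrows)), int(rng.integers(ncols)))
            for _ in range(n_patches)
        ]
        layers.append(_distance_layer(patches, nrows, ncols, cell_size))
        names.append(name)
        info_patches[name] = patches
    mask = np.zeros((nrows, ncols), dtype=bool)
    if nodata_fraction > 0:
        n_bad = int(round(nodata_fraction * nrows * ncols))
        flat = rng.choice(nrows * ncols, size=n_bad, replace=False)
        mask.flat[flat] = True
    stack = EnvStack(names, np.stack(layers), cell_size, (0.0, 0.0), mask)
    info = LandscapeInfo(names[:n_climate_layers], names[n_climate_layers:],
                         info_patches)
    return stack, info


def _distance_layer(patches: Sequence[Cell], nrows: int, ncols: int,
                    cell_size: float) -> np.ndarray:
    occ = np.ones((nrows, ncols), dtype=bool)
    for r, c in patches:
        occ[r, c] = False
    return ndimage.distance_transform_edt(occ) * cell_size


# ---------------------------------------------------------------------------
# Phylogeny and niche evolution
# ---------------------------------------------------------------------------

def simulate_tree_and_niches(
    n_species: int,
    n_layers: int,
    bm_rate: float = 1.0,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    seed: int = 0,
) -> VirtualTruth:
    """Birth–death tree (unit height) with Brownian-motion niche optima.

    Optima are in standardized (z-score) units per layer; with
    ``bm_rate == 0`` every tip inherits the root state (all zeros).
    """
    if n_species < 4:
        raise InputError("need at least 4 species")
    if death_rate >= birth_rate:
        raise InputError("death_rate must be below birth_rate")
    pyrng = random.Random(int(seed))
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_species,
        rng=pyrng,
        repeat_until_success=True,
    )
    # relabel tips deterministically and scale to unit height
    width = len(str(n_species))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i:0{width}d}"
    height = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    if height <= 0:
        raise InputError("degenerate tree of zero height")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / height

    rng = np.random.default_rng(seed)
    states: dict[int, np.ndarray] = {}
    tips: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            val = np.zeros(n_layers)
        else:
            bl = node.edge.length or 0.0
            step = rng.standard_normal(n_layers) * np.sqrt(bm_rate * bl)
            val = states[id(node.parent_node)] + step
        states[id(node)] = val
        if node.is_leaf():
            tips[node.taxon.label] = val
    optima = pd.DataFrame.from_dict(tips, orient="index").sort_index()
    optima.columns = [f"layer{j}" for j in range(n_layers)]
    return VirtualTruth(tree=tree, niche_optima=optima)


def true_suitability(
    stack: EnvStack, optimum: np.ndarray, breadth: np.ndarray
) -> np.ndarray:
    """Gaussian-niche suitability surface in [0, 1].

    ``suit(cell) = exp(-0.5 * sum_v ((x_v - opt_v) / breadth_v)^2)`` with
    optimum and breadth in raw layer units.  Nodata cells are NaN.
    """
    optimum = np.asarray(optimum, dtype=float)
    breadth = np.asarray(breadth, dtype=float)
    if np.any(breadth <= 0):
        raise InputError("niche breadths must be positive")
    z = (stack.values - optimum[:, None, None]) / breadth[:, None, None]
    suit = np.exp(-0.5 * np.sum(z**2, axis=0))
    suit[stack.nodata_mask] = np.nan
    return suit


def sample_occurrences(
    truth_grid: np.ndarray,
    n: int,
    seed: int | np.random.Generator,
    stack: EnvStack,
    species_id: str = "species",
) -> OccurrenceSet:
    """Draw occupied cells without replacement, probability ∝ suitability.

    Supports samples as small as n = 2 (the rare-species target).  If fewer
    cells have positive suitability than requested the draw is capped with
    a warning.  Points are placed at cell centers.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    suit = np.nan_to_num(np.asarray(truth_grid, dtype=float), nan=0.0)
    suit[stack.nodata_mask] = 0.0
    rows, cols = np.nonzero(suit > 0)
    weights = suit[rows, cols]
    if rows.size < n:
        warnings.warn(
            f"{species_id}: only {rows.size} cells with positive suitability, capping n"
        )
        n = rows.size
    if n == 0:
        raise InputError(f"{species_id}: no cell with positive suitability")
    pick = rng.choice(rows.size, size=n, replace=False, p=weights / weights.sum())
    cells = [(int(rows[i]), int(cols[i])) for i in pick]
    points = [stack.cell_center(c) for c in cells]
    return OccurrenceSet(species_id, points, cells)


# ---------------------------------------------------------------------------
# Future scenarios
# ---------------------------------------------------------------------------

def make_future_scenarios(
    current: EnvStack,
    info: LandscapeInfo,
    climate_shift: np.ndarray | Sequence[float],
    lulc_regenerate_fraction: float = 0.5,
    n_gcm: int = 3,
    gcm_jitter_sd: float = 0.1,
    seed: int = 0,
) -> ScenarioSet:
    """Build the full scenario factorial the projection pipeline consumes.

    * dynamic climate: climate layers shifted by ``climate_shift`` (× 0.5
      for the mild SSP, × 1 for the severe one) plus GCM-specific additive
      jitter; LULC layers copied bit-identically from ``current``.
    * dynamic LULC: climate copied bit-identically; a fraction of the LULC
      seed patches relocated (half the fraction under the mild SSP) and the
      distance layers recomputed.
    * dynamic both: both perturbations applied.
    """
    if n_gcm < 1:
        raise InputError("n_gcm must be >= 1")
    shift = np.asarray(climate_shift, dtype=float)
    if shift.shape != (len(info.climate_layers),):
        raise InputError("climate_shift must have one entry per climate layer")
    rng = np.random.default_rng(seed)
    gcms = [f"gcm{g + 1}" for g in range(n_gcm)]
    jitter = {g: rng.normal(0.0, gcm_jitter_sd, size=shift.shape) for g in gcms}
    ssp_scale = {MILD: 0.5, SEVERE: 1.0}

    # future LULC patch layouts, one per SSP
    lulc_future: dict[str, dict[str, list[Cell]]] = {}
    for ssp, scale in ssp_scale.items():
        frac = lulc_regenerate_fraction * scale
        layout: dict[str, list[Cell]] = {}
        for name, patches in info.lulc_patches.items():
            n_move = int(round(frac * len(patches)))
            moved = list(patches)
            if n_move > 0:
                which = rng.choice(len(patches), size=n_move, replace=False)
                for j in which:
                    moved[j] = (
                        int(rng.integers(current.nrows)),
                        int(rng.integers(current.ncols)),
                    )
            layout[name] = moved
        lulc_future[ssp] = layout

    def climate_values(gcm: str, ssp: str) -> np.ndarray:
        vals = current.values.copy()
        for i, name in enumerate(info.climate_layers):
            k = current.layer_names.index(name)
            vals[k] = vals[k] + ssp_scale[ssp] * shift[i] + jitter[gcm][i]
        return vals

    def lulc_values(base: np.ndarray, ssp: str) -> np.ndarray:
        vals = base
        for name in info.lulc_layers:
            k = current.layer_names.index(name)
            vals[k] = _distance_layer(
                lulc_future[ssp][name], current.nrows, current.ncols,
                current.cell_size,
            )
        return vals

    def mk(vals: np.ndarray) -> EnvStack:
        return EnvStack(
            list(current.layer_names), vals, current.cell_size,
            tuple(current.origin), current.nodata_mask.copy(),
        )

    stacks: dict[tuple[str, str | None, str | None], EnvStack] = {
        (SCENARIO_CURRENT, None, None): current.copy()
    }
    for ssp in ssp_scale:
        stacks[(SCENARIO_LULC, None, ssp)] = mk(
            lulc_values(current.values.copy(), ssp)
        )
        for gcm in gcms:
            stacks[(SCENARIO_CLIMATE, gcm, ssp)] = mk(climate_values(gcm, ssp))
            stacks[(SCENARIO_BOTH, gcm, ssp)] = mk(
                lulc_values(climate_values(gcm, ssp), ssp)
            )
    return ScenarioSet(stacks)


# ---------------------------------------------------------------------------
# Default fixture
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    """A complete simulated study system with ground truth."""

    stack: EnvStack
    info: LandscapeInfo
    truth: VirtualTruth
    occurrences: dict[str, OccurrenceSet]
    scenarios: ScenarioSet


def _tier_counts(n_species: int, rng: np.random.Generator) -> list[int]:
    """Occurrence counts populating all three modelling tiers.

    Roughly 40% rare (< 15 cells, incl. 2–4-cell species), 30% mid
    (15–30), 30% data-rich (> 30).
    """
    n_rare = max(4, int(round(0.4 * n_species)))
    n_mid = max(2, int(round(0.3 * n_species)))
    n_rich = n_species - n_rare - n_mid
    counts = []
    # guarantee species at the extension boundary (2, 3, 4 references)
    boundary = [2, 3, 4]
    for i in range(n_rare):
        if i < len(boundary):
            counts.append(boundary[i])
        else:
            counts.append(int(rng.integers(5, 15)))
    counts += [int(rng.integers(15, 31)) for _ in range(n_mid)]
    counts += [int(rng.integers(31, 61)) for _ in range(n_rich)]
    return counts


def make_fixture(
    nrows: int = 60,
    ncols: int = 60,
    n_climate: int = 5,
    n_lulc: int = 3,
    n_species: int = 32,
    bm_rate: float = 1.0,
    breadth_range: tuple[float, float] = (0.6, 1.4),
    climate_shift_sd: float = 1.0,
    seed: int = 0,
) -> Fixture:
    """Build the default study system: landscape, clade, occurrences, futures.

    Niche optima (z-units from Brownian motion) are mapped to raw layer
    units via each layer's valid-cell mean/sd; breadths are drawn uniformly
    in sd units.  Occurrence counts are allocated so the three modelling
    tiers (< 15, 15–30, > 30 cells) are all populated, including species
    with only 2–4 cells.
    """
    rng = np.random.default_rng(seed)
    stack, info = simulate_landscape(
        nrows, ncols, n_climate, n_lulc, spatial_corr_range=5.0,
        seed=int(rng.integers(2**31)),
    )
    truth = simulate_tree_and_niches(
        n_species, stack.n_layers, bm_rate=bm_rate,
        seed=int(rng.integers(2**31)),
    )
    valid = ~stack.nodata_mask
    layer_mean = np.array([stack.values[i][valid].mean() for i in range(stack.n_layers)])
    layer_sd = np.array([stack.values[i][valid].std() for i in range(stack.n_layers)])
    breadths = {}
    counts = _tier_counts(n_species, rng)
    # shuffle so rarity is spread across the tree (tips are in leaf order):
    # rare species then have well-sampled relatives, as in real clades
    counts = [counts[i] for i in rng.permutation(n_species)]
    for sp, n_occ in zip(truth.species, counts):
        z_opt = truth.niche_optima.loc[sp].to_numpy()
        z_br = rng.uniform(*breadth_range, size=stack.n_layers)
        optimum = layer_mean + z_opt * layer_sd
        breadth = z_br * layer_sd
        breadths[sp] = z_br
        suit = true_suitability(stack, optimum, breadth)
        truth.true_suitability[sp] = suit
        truth.occurrence_counts[sp] = n_occ
    truth.niche_breadths = pd.DataFrame.from_dict(
        breadths, orient="index", columns=truth.niche_optima.columns
    ).sort_index()
    occurrences = {
        sp: sample_occurrences(
            truth.true_suitability[sp], truth.occurrence_counts[sp],
            int(rng.integers(2**31)), stack, species_id=sp,
        )
        for sp in truth.species
    }
    shift = rng.normal(0.0, climate_shift_sd, size=n_climate)
    scenarios = make_future_scenarios(
        stack, info, shift, lulc_regenerate_fraction=0.6,
        n_gcm=3, gcm_jitter_sd=0.2, seed=int(rng.integers(2**31)),
    )
    return Fixture(stack, info, truth, occurrences, scenarios)


# ---------------------------------------------------------------------------
# Fixture persistence (text formats: .asc rasters, CSV, Newick, JSON)
# ---------------------------------------------------------------------------

def _key_to_dirname(key: tuple[str, str | None, str | None]) -> str:
    return "__".join("none" if p is None else p for p in key)


def _dirname_to_key(name: str) -> tuple[str, str | None, str | None]:
    parts = [None if p == "none" else p for p in name.split("__")]
    return tuple(parts)  # type: ignore[return-value]


def save_fixture(fixture: Fixture, directory) -> None:
    """Write a fixture to disk: rasters per scenario, occurrences CSV,
    Newick tree and a truth.json with optima, breadths and counts."""
    import json
    from pathlib import Path

    from .geodata import write_env_stack

    directory = Path(directory)
    for key, stack in fixture.scenarios.stacks.items():
        write_env_stack(stack, directory / "scenarios" / _key_to_dirname(key))
    rows = []
    for sp, occ in sorted(fixture.occurrences.items()):
        for (x, y), (r, c) in zip(occ.points, occ.cell_ids):
            rows.append({"species": sp, "x": x, "y": y, "row": r, "col": c})
    pd.DataFrame(rows).to_csv(directory / "occurrences.csv", index=False)
    fixture.truth.tree.write(path=str(directory / "tree.nwk"), schema="newick")
    truth = {
        "niche_optima": fixture.truth.niche_optima.to_dict(orient="index"),
        "niche_breadths": (
            fixture.truth.niche_breadths.to_dict(orient="index")
            if fixture.truth.niche_breadths is not None else None
        ),
        "occurrence_counts": fixture.truth.occurrence_counts,
        "climate_layers": fixture.info.climate_layers,
        "lulc_layers": fixture.info.lulc_layers,
        "lulc_patches": {k: [list(c) for c in v]
                         for k, v in fixture.info.lulc_patches.items()},
    }
    (directory / "truth.json").write_text(json.dumps(truth, indent=2))


def load_fixture(directory) -> Fixture:
    """Read back a fixture written by :func:`save_fixture`."""
    import json
    from pathlib import Path

    from .geodata import load_env_stack

    directory = Path(directory)
    stacks = {}
    for sub in sorted((directory / "scenarios").iterdir()):
        key = _dirname_to_key(sub.name)
        paths = sorted(sub.glob("*.asc"))
        stacks[key] = load_env_stack(paths)
    scenarios = ScenarioSet(stacks)
    current = scenarios.current
    truth_raw = json.loads((directory / "truth.json").read_text())
    tree = dendropy.Tree.get(path=str(directory / "tree.nwk"),
                             schema="newick")
    optima = pd.DataFrame.from_dict(truth_raw["niche_optima"],
                                    orient="index").sort_index()
    breadths = (
        pd.DataFrame.from_dict(truth_raw["niche_breadths"],
                               orient="index").sort_index()
        if truth_raw["niche_breadths"] else None
    )
    truth = VirtualTruth(tree=tree, niche_optima=optima,
                         niche_breadths=breadths,
                         occurrence_counts={
                             k: int(v)
                             for k, v in truth_raw["occurrence_counts"].items()
                         })
    occ_df = pd.read_csv(directory / "occurrences.csv")
    occurrences = {}
    for sp, g in occ_df.groupby("species"):
        occurrences[str(sp)] = OccurrenceSet(
            str(sp),
            list(zip(g["x"], g["y"])),
            [(int(r), int(c)) for r, c in zip(g["row"], g["col"])],
        )
    info = LandscapeInfo(
        list(truth_raw["climate_layers"]), list(truth_raw["lulc_layers"]),
        {k: [tuple(c) for c in v]
         for k, v in truth_raw["lulc_patches"].items()},
    )
    return Fixture(current, info, truth, occurrences, scenarios)
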