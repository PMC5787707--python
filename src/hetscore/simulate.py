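"""Synthetic arrayed-screen generator.

Emulates the statistical structure the within-well scoring method assumes:
each well holds a mixed population of wild-type and genetically perturbed
cells. A cell is transfected (T(+)) with probability ``transfection_rate``;
within a targeting well each T(+) cell is actually perturbed with
probability ``penetrance`` (CRISPR editing is incomplete). Wild-type
features are independent unit-variance Gaussians; a perturbation shifts
the mean by ``effect_vector`` (units of wild-type SD). Technical structure
is additive: a per-well offset vector ~ N(0, well_sigma^2) per feature and
linear row/column plate gradients.

The generator is seeded per well from (seed, plate, well), so the draws for
one well never depend on how many other wells are simulated.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import PLATE_ROWS, substream_rng, well_position
from .io import CellTable, PlateMap

# outer two columns on each side left empty, mirroring edge-well exclusion
USABLE_COLS = list(range(3, 23))  # 1-based columns 3..22
USABLE_ROWS = list(PLATE_ROWS)   # A..P


def default_effect_vector(n_features: int, magnitude: float = 3.0, index: int = 0) -> np.ndarray:
    """A mean shift of ``magnitude`` wild-type SDs on a single feature."""
    v = np.zeros(n_features)
    v[index] = magnitude
    return v


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for one synthetic screen.

    Defaults describe a desk-scale arrayed screen: 96 used wells on a
    384-well plate, ~2000 analysed cells per well, half the cells
    transfected, 60% of transfected cells functionally perturbed, and a
    3-SD single-feature perturbation effect.
    """

    n_plates: int = 1
    wells_per_plate: int = 96
    cells_per_well: int = 2000
    transfection_rate: float = 0.5
    penetrance: float = 0.6
    n_features: int = 20
    effect_vector: Sequence[float] | None = None
    well_sigma: float = 0.3
    row_effect: float = 0.01
    col_effect: float = 0.01
    control_fraction: float = 0.125
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("transfection_rate", "penetrance", "control_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.cells_per_well < 1:
            raise ValueError("cells_per_well must be >= 1")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.well_sigma < 0:
            raise ValueError("well_sigma must be >= 0")
        if self.wells_per_plate > len(USABLE_ROWS) * len(USABLE_COLS):
            raise ValueError("wells_per_plate exceeds usable plate positions")
        if self.effect_vector is None:
            self.effect_vector = default_effect_vector(self.n_features)
        self.effect_vector = np.asarray(self.effect_vector, dtype=float)
        if self.effect_vector.shape != (self.n_features,):
            raise ValueError("effect_vector length must equal n_features")

    @property
    def feature_names(self) -> list[str]:
        return [f"f{i:02d}" for i in range(self.n_features)]


@dataclasses.dataclass(frozen=True)
class WellSpec:
    """Layout entry for one well; ``effect_vector=None`` means the config default."""

    plate: str
    well: str
    perturbation: str
    gene: str
    guide: str
    is_control: bool
    effect_vector: tuple[float, ...] | None = None


def default_well_plan(cfg: SimulationConfig) -> list[WellSpec]:
    """Row-major layout; control wells spread evenly across each plate."""
    plan: list[WellSpec] = []
    positions = [(r, c) for r in USABLE_ROWS for c in USABLE_COLS][: cfg.wells_per_plate]
    n_ctl = int(round(cfg.control_fraction * cfg.wells_per_plate))
    if cfg.control_fraction > 0:
        n_ctl = max(n_ctl, 1)
    ctl_idx = set(np.linspace(0, cfg.wells_per_plate - 1, n_ctl).round().astype(int)) if n_ctl else set()
    for p in range(cfg.n_plates):
        plate = f"P{p + 1:02d}"
        for i, (r, c) in enumerate(positions):
            well = f"{r}{c:02d}"
            if i in ctl_idx:
                plan.append(WellSpec(plate, well, f"NT_{plate}_{well}", "NT", "nt", True))
            else:
                gidx = p * cfg.wells_per_plate + i
                plan.append(
                    WellSpec(plate, well, f"PT_{plate}_{well}", f"GENE{gidx:04d}", f"g{gidx:04d}", False)
                )
    return plan


def _simulate_well(cfg: SimulationConfig, spec: WellSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    rng = substream_rng(cfg.seed, spec.plate, spec.well)
    n = max(1, int(rng.poisson(cfg.cells_per_well)))
    offset = rng.normal(0.0, cfg.well_sigma, size=cfg.n_features) if cfg.well_sigma > 0 else np.zeros(cfg.n_features)
    row, col = well_position(spec.well)
    gradient = cfg.row_effect * row + cfg.col_effect * col
    transfected = rng.random(n) < cfg.transfection_rate
    if spec.is_control:
        effect = np.zeros(cfg.n_features)
    elif spec.effect_vector is not None:
        effect = np.asarray(spec.effect_vector, dtype=float)
    else:
        effect = np.asarray(cfg.effect_vector, dtype=float)
    u_pen = rng.random(n)  # drawn for every well to keep streams aligned
    if spec.is_control:
        perturbed = np.zeros(n, dtype=bool)
    else:
        perturbed = transfected & (u_pen < cfg.penetrance)
    X = rng.standard_normal((n, cfg.n_features)) + offset + gradient
    X[perturbed] += effect
    cells = pd.DataFrame(
        {"plate": spec.plate, "well": spec.well, "cell": np.arange(n), "transfected": transfected}
    )
    for j, name in enumerate(cfg.feature_names):
        cells[name] = X[:, j]
    truth = pd.DataFrame(
        {"plate": spec.plate, "well": spec.well, "cell": np.arange(n), "perturbed": perturbed}
    )
    return cells, truth


def generate_screen(
    cfg: SimulationConfig, well_plan: Sequence[WellSpec] | None = None
) -> tuple[CellTable, PlateMap, pd.DataFrame]:
    """Simulate a whole screen.

    Returns the cell table, the plate map, and a truth table recording the
    latent perturbed status of each cell. Identical config (and plan) gives
    identical outputs.
    """
    plan = list(well_plan) if well_plan is not None else default_well_plan(cfg)
    cell_frames, truth_frames = [], []
    for spec in plan:
        cells, truth = _simulate_well(cfg, spec)
        cell_frames.append(cells)
        truth_frames.append(truth)
    cells = CellTable(pd.concat(cell_frames, ignore_index=True), cfg.feature_names)
    pmap = PlateMap(
        pd.DataFrame(
            {
                "plate": [s.plate for s in plan],
                "well": [s.well for s in plan],
                "perturbation": [s.perturbation for s in plan],
                "gene": [s.gene for s in plan],
                "guide": [s.guide for s in plan],
                "is_control": [s.is_control for s in plan],
            }
        )
    )
    truth = pd.concat(truth_frames, ignore_index=True)
    return cells, pmap, truth


def generate_guide_fixture(seed: int) -> tuple[dict, pd.DataFrame]:
    """Toy gene models and guide candidates for the library-design rules.

    Each gene has 2-6 transcripts sharing a pool of exon regions; candidate
    guides carry on-target scores on a fixed 0.05 grid so every threshold
    in (0, 1) has candidates on both sides.
    """
    rng = substream_rng(seed, "guide-fixture")
    genes: dict[str, dict[str, list[str]]] = {}
    rows = []
    score_grid = np.round(np.arange(0.05, 1.0, 0.05), 2)
    for g in range(6):
        gene = f"G{g:02d}"
        n_regions = int(rng.integers(4, 9))
        regions = [f"{gene}_E{i:02d}" for i in range(n_regions)]
        n_tx = int(rng.integers(2, 7))
        transcripts = {}
        for t in range(n_tx):
            # contiguous exon run keeps 5'->3' order meaningful
            lo = int(rng.integers(0, max(1, n_regions - 2)))
            hi = int(rng.integers(lo + 1, n_regions)) + 1
            transcripts[f"{gene}_T{t}"] = regions[lo:hi]
        genes[gene] = transcripts
        n_cand = int(rng.integers(6, 13))
        for c in range(n_cand):
            region = regions[int(rng.integers(0, n_regions))]
            hit_tx = [tid for tid, ex in transcripts.items() if region in ex]
            if not hit_tx:
                continue
            rows.append(
                {
                    "guide": f"{gene}_c{c:02d}",
                    "gene": gene,
                    "exon_region": region,
                    "score": float(rng.choice(score_grid)),
                    "transcripts_hit": ";".join(sorted(hit_tx)),
                }
            )
    return genes, pd.DataFrame(rows)
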