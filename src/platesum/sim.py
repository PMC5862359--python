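"""Simulation of scRNA-seq counts with confounded plate effects.

Counts are generated under a hierarchical model: each gene ``i`` has a base
expected count ``mu_ig`` per group ``g``; every plate ``k`` carries a gene-
and plate-specific multiplicative effect ``delta_ikg`` (log-normal, unit
mean) shared by all cells on the plate; every cell ``j`` carries a scalar
factor ``theta_jkg`` (log-normal, unit mean) modelling capture efficiency /
library size. Conditional on the realized factors, the count for gene ``i``
in cell ``j`` is negative-binomial with mean ``delta * theta * mu`` and
gene-specific dispersion ``phi``, independent across genes and cells.

Because every plate holds cells of a single group, the plate effect is
confounded with the group contrast: it cannot be removed by per-cell
scaling normalization, and ignoring it induces within-plate dependence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SimulationConfig",
    "PlateDesign",
    "SimulatedDataset",
    "sample_plate_effects",
    "sample_cell_factors",
    "spike_de",
    "simulate_dataset",
    "scenario",
    "SCENARIOS",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a plate-confounded scRNA-seq experiment.

    Parameters
    ----------
    n_genes
        Number of genes simulated.
    n_groups
        Number of biological groups (each group gets its own plates).
    plates_per_group
        Plates nested in each group; every plate holds cells of one group.
    cells_per_plate_range
        Inclusive ``(lo, hi)``; the number of cells on each plate is drawn
        uniformly from this interval.
    mean_log_mu, sd_log_mu
        Location/scale (natural-log scale) of the log-normal distribution of
        base expected counts ``mu_i``.
    nb_dispersion
        Median per-gene NB dispersion ``phi`` (variance ``mu + phi*mu^2``).
    nb_dispersion_log_sd
        Log-scale spread of per-gene dispersions; 0 makes them constant.
    sigma_plate
        Standard deviation of ``log(delta)``; 0 disables the plate effect.
    sigma_theta
        Standard deviation of ``log(theta)`` (cell-factor variability).
    zero_inflation
        Optional dropout probability: each count is independently replaced
        by zero with this probability (zero-inflated NB).
    de_fraction, de_log2fc
        Fraction of genes spiked as differentially expressed between the
        two groups, and the magnitude of the spiked log2 fold change.
    seed
        Root seed; a single deterministic stream is consumed in documented
        order (see :func:`simulate_dataset`).
    """

    n_genes: int = 10_000
    n_groups: int = 2
    plates_per_group: int = 3
    cells_per_plate_range: tuple[int, int] = (50, 100)
    mean_log_mu: float = math.log(5.0)
    sd_log_mu: float = 1.5
    nb_dispersion: float = 0.3
    nb_dispersion_log_sd: float = 0.5
    sigma_plate: float = 0.5
    sigma_theta: float = 0.3
    zero_inflation: float | None = None
    de_fraction: float = 0.0
    de_log2fc: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cells_per_plate_range
        if self.n_genes < 1 or self.n_groups < 1 or self.plates_per_group < 1:
            raise ValueError("n_genes, n_groups and plates_per_group must be positive")
        if lo < 1 or lo > hi:
            raise ValueError(f"invalid cells_per_plate_range ({lo}, {hi})")
        if self.sigma_plate < 0 or self.sigma_theta < 0:
            raise ValueError("sigma_plate and sigma_theta must be non-negative")
        if self.nb_dispersion < 0 or self.nb_dispersion_log_sd < 0:
            raise ValueError("nb_dispersion and nb_dispersion_log_sd must be non-negative")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.zero_inflation is not None and not 0.0 <= self.zero_inflation < 1.0:
            raise ValueError("zero_inflation must lie in [0, 1)")

    @property
    def n_plates(self) -> int:
        return self.n_groups * self.plates_per_group


@dataclass(frozen=True)
class PlateDesign:
    """Per-cell plate/group labels plus derived per-plate group labels.

    Plates partition the cells and each plate belongs to exactly one group
    (the confounded design: group contrasts coincide with between-plate
    contrasts).
    """

    cell_plate: np.ndarray
    cell_group: np.ndarray
    plates: np.ndarray = field(init=False)
    plate_group: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        cell_plate = np.asarray(self.cell_plate)
        cell_group = np.asarray(self.cell_group)
        if cell_plate.shape != cell_group.shape or cell_plate.ndim != 1:
            raise ValueError("cell_plate and cell_group must be 1-D and equal length")
        if cell_plate.size == 0:
            raise ValueError("design has no cells")
        # first-appearance plate order, kept stable for downstream column order
        plates, first = np.unique(cell_plate, return_index=True)
        order = np.argsort(first)
        plates = plates[order]
        plate_group = np.empty(plates.shape, dtype=cell_group.dtype)
        for idx, plate in enumerate(plates):
            groups = np.unique(cell_group[cell_plate == plate])
            if groups.size != 1:
                raise ValueError(
                    f"plate {plate!r} spans groups {list(groups)}; every plate must "
                    "hold cells from a single group"
                )
            plate_group[idx] = groups[0]
        object.__setattr__(self, "cell_plate", cell_plate)
        object.__setattr__(self, "cell_group", cell_group)
        object.__setattr__(self, "plates", plates)
        object.__setattr__(self, "plate_group", plate_group)

    @property
    def n_cells(self) -> int:
        return self.cell_plate.size

    @property
    def n_plates(self) -> int:
        return self.plates.size

    @property
    def groups(self) -> np.ndarray:
        """Distinct group labels in first-appearance order."""
        labels, first = np.unique(self.cell_group, return_index=True)
        return labels[np.argsort(first)]

    def plate_index(self) -> np.ndarray:
        """Integer plate index per cell (into ``self.plates``)."""
        lookup = {p: i for i, p in enumerate(self.plates)}
        return np.array([lookup[p] for p in self.cell_plate], dtype=np.intp)


@dataclass(frozen=True)
class SimulatedDataset:
    """Realized counts plus the latent factors and DE ground truth."""

    counts: np.ndarray  # gene x cell, non-negative integers
    design: PlateDesign
    plate_effects: np.ndarray  # gene x plate, realized delta
    cell_factors: np.ndarray  # per cell, realized theta
    true_de: np.ndarray  # per gene bool
    true_log2fc: np.ndarray  # per gene, signed; 0 for non-DE
    config: SimulationConfig

    def __post_init__(self) -> None:
        if self.counts.shape[1] != self.design.n_cells:
            raise ValueError("counts and design disagree on the number of cells")
        if (self.true_de != (self.true_log2fc != 0)).any():
            raise ValueError("true_de must coincide with true_log2fc != 0")


def _unit_mean_lognormal(shape: tuple[int, ...], sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return np.ones(shape)
    # location -sigma^2/2 makes E[exp(X)] exactly 1
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)


def sample_plate_effects(
    n_genes: int, n_plates: int, sigma_plate: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw the gene x plate matrix of multiplicative plate effects.

    Entries are i.i.d. ``LogNormal(-sigma_plate^2 / 2, sigma_plate^2)`` so the
    mean is exactly 1; ``sigma_plate = 0`` returns all ones (no plate effect).
    """
    return _unit_mean_lognormal((n_genes, n_plates), sigma_plate, rng)


def sample_cell_factors(n_cells: int, sigma_theta: float, rng: np.random.Generator) -> np.ndarray:
    """Draw per-cell scaling factors, log-normal with mean exactly 1."""
    return _unit_mean_lognormal((n_cells,), sigma_theta, rng)


def spike_de(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Choose DE genes and build per-group mean multipliers.

    A uniformly random subset of ``floor(de_fraction * n_genes)`` genes is
    marked DE; each DE gene is up-regulated in one of the two groups (chosen
    with probability 1/2) by a factor ``2**de_log2fc``.

    Returns
    -------
    true_de : bool array (n_genes,)
    true_log2fc : float array (n_genes,), log2(group2 mean / group1 mean)
    multipliers : float array (n_genes, n_groups) applied to ``mu_i``
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_genes
    true_de = np.zeros(n, dtype=bool)
    multipliers = np.ones((n, config.n_groups))
    if config.de_fraction == 0:
        return true_de, np.zeros(n), multipliers
    if config.n_groups != 2:
        raise ValueError("DE spike-in requires exactly two groups")
    n_de = int(math.floor(config.de_fraction * n))
    chosen = rng.choice(n, size=n_de, replace=False)
    up_in_second = rng.random(n_de) < 0.5
    true_de[chosen] = True
    multipliers[chosen[up_in_second], 1] = 2.0**config.de_log2fc
    multipliers[chosen[~up_in_second], 0] = 2.0**config.de_log2fc
    true_log2fc = np.log2(multipliers[:, 1] / multipliers[:, 0])
    return true_de, true_log2fc, multipliers


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Simulate a full dataset under the plate-effect model.

    One :class:`numpy.random.Generator` seeded from ``config.seed`` is
    consumed in a fixed, documented order — cells per plate, DE spike-in,
    base means, dispersions, plate effects, cell factors, counts, dropout —
    so identical configs yield bit-identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.cells_per_plate_range
    n_plates = config.n_plates

    cells_per_plate = rng.integers(lo, hi + 1, size=n_plates)
    plate_labels = np.array([f"P{k + 1:02d}" for k in range(n_plates)])
    group_labels = np.array([f"G{g + 1}" for g in range(config.n_groups)])
    plate_group_idx = np.repeat(np.arange(config.n_groups), config.plates_per_group)
    cell_plate = np.repeat(plate_labels, cells_per_plate)
    cell_group = np.repeat(group_labels[plate_group_idx], cells_per_plate)
    design = PlateDesign(cell_plate=cell_plate, cell_group=cell_group)

    true_de, true_log2fc, multipliers = spike_de(config, rng)
    mu = rng.lognormal(mean=config.mean_log_mu, sigma=config.sd_log_mu, size=config.n_genes)
    if config.nb_dispersion_log_sd > 0 and config.nb_dispersion > 0:
        phi = config.nb_dispersion * rng.lognormal(
            mean=0.0, sigma=config.nb_dispersion_log_sd, size=config.n_genes
        )
    else:
        phi = np.full(config.n_genes, config.nb_dispersion)

    delta = sample_plate_effects(config.n_genes, n_plates, config.sigma_plate, rng)
    theta = sample_cell_factors(design.n_cells, config.sigma_theta, rng)

    cell_plate_idx = np.repeat(np.arange(n_plates), cells_per_plate)
    cell_group_idx = plate_group_idx[cell_plate_idx]
    mean = (
        mu[:, None]
        * multipliers[:, cell_group_idx]
        * delta[:, cell_plate_idx]
        * theta[None, :]
    )

    if np.all(phi == 0):
        counts = rng.poisson(mean)
    else:
        # gamma-Poisson mixture: NB(mean, var = mean + phi * mean^2)
        shape = np.where(phi > 0, 1.0 / np.maximum(phi, 1e-300), np.inf)[:, None]
        lam = np.where(
            phi[:, None] > 0,
            rng.gamma(np.broadcast_to(shape, mean.shape), np.maximum(phi[:, None] * mean, 1e-300)),
            mean,
        )
        counts = rng.poisson(lam)

    if config.zero_inflation is not None and config.zero_inflation > 0:
        dropout = rng.random(counts.shape) < config.zero_inflation
        counts = np.where(dropout, 0, counts)

    return SimulatedDataset(
        counts=counts.astype(np.int64),
        design=design,
        plate_effects=delta,
        cell_factors=theta,
        true_de=true_de,
        true_log2fc=true_log2fc,
        config=config,
    )


#: Named study scenarios: the default confounded design plus perturbations
#: probing robustness (weaker plate effect, noisier library sizes, uneven
#: plate sizes, more replication, zero inflation).
SCENARIOS: dict[str, dict] = {
    "default": {},
    "no_plate_effect": {"sigma_plate": 0.0},
    "half_plate_effect": {"sigma_plate": 0.25},
    "variable_libsizes": {"sigma_theta": 0.6},
    "variable_cell_numbers": {"cells_per_plate_range": (20, 130)},
    "more_plates": {"plates_per_group": 6},
    "zinb": {"zero_inflation": 0.2},
}


def scenario(name: str, **overrides) -> SimulationConfig:
    """Return the configuration of a named simulation scenario.

    ``overrides`` are applied after the scenario's own modification (useful
    for scaling ``n_genes`` or setting seeds/DE spike-ins).
    """
    try:
        changes = SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; valid scenarios: {sorted(SCENARIOS)}"
        ) from None
    return replace(SimulationConfig(), **{**changes, **overrides})
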