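"""Ground-truth networks and synthetic expression data.

Benchmarking inference without downloadable data requires a generator that
emulates the growth-plate study design: a handful of independent studies of
8–18 microarray samples each, with zonal sampling along the growth plate
(resting → proliferating → maturing → hypertrophic), treatment/control
contrasts and knockout-style perturbations.

The default generator is a steady-state linear-Gaussian system: the signed
weighted adjacency A of a known ground-truth network is scaled to spectral
radius < 1 and each sample solves

    x = Aᵀ·x + u,        u = design-specific perturbation + noise

so the expression vector is the stationary response to a small perturbation
of every gene at once (multifactorial data), to a single-gene knockout, or
to a graded zonal stimulus on declared driver genes.  The linear form keeps
the signal analytically controllable for inference benchmarks; trajectories
of the logical model can be sampled instead for cross-module tests.

The module also packages the growth-plate fixture: the 13 transcription
factors used for inference and the curated prior sign matrix over them.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .inference import ExpressionMatrix
from .network import (
    Edge,
    Node,
    NodeAliasTable,
    PriorMatrix,
    RegulatoryNetwork,
)

ZONE_NAMES = ("Resting", "Proliferating", "Maturing", "Hypertrophic")
DESIGNS = ("multifactorial", "knockout", "zones", "treatment")


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic data set.

    Defaults mirror the growth-plate benchmark: 13 genes, edge density
    0.15, 60 multifactorial samples, measurement noise SD 0.25 on unit-SD
    perturbations.  A seed is mandatory: every stochastic call derives its
    randomness from it.
    """

    seed: int
    n_genes: int = 13
    edge_density: float = 0.15
    activating_fraction: float = 0.75
    design: str = "multifactorial"
    n_samples: int = 60
    noise_sd: float = 0.25
    perturbation_sd: float = 1.0
    spectral_radius: float = 0.8
    n_zones: int = 4
    n_replicates: int = 2
    zone_drivers: list[str] = field(default_factory=list)
    treatment_targets: list[str] = field(default_factory=list)
    treatment_effect: float = 1.0
    study: str = "synthetic"

    def __post_init__(self):
        if not 0.0 < self.edge_density < 1.0:
            raise ValueError("edge_density must be in (0, 1)")
        if not 0.0 <= self.activating_fraction <= 1.0:
            raise ValueError("activating_fraction must be in [0, 1]")
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; choose from {DESIGNS}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class SyntheticDataset:
    truth: RegulatoryNetwork
    expr: ExpressionMatrix
    provenance: GeneratorConfig

    def provenance_dict(self) -> dict:
        return asdict(self.provenance)


# ---------------------------------------------------------------------------
# Network generation
# ---------------------------------------------------------------------------

def generate_network(config: GeneratorConfig) -> RegulatoryNetwork:
    """Random signed directed graph without self-loops.

    Each ordered non-self pair carries an edge with probability
    ``edge_density`` (expected edge count density·n·(n−1)); signs are +1
    with probability ``activating_fraction``; weights uniform in
    [0.5, 1.5].  Resamples (bounded retries) until the graph is non-empty
    and every node has at least one incident edge.
    """
    n = config.n_genes
    if n < 2:
        raise ValueError("need at least 2 genes")
    if config.edge_density * n * (n - 1) < 1.0:
        raise ValueError("edge_density too low: expected edge count below 1")
    rng = np.random.default_rng(config.seed)
    names = [f"G{i + 1:02d}" for i in range(n)]
    for _ in range(200):
        edges = []
        touched = set()
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if rng.random() < config.edge_density:
                    sign = 1 if rng.random() < config.activating_fraction else -1
                    weight = float(rng.uniform(0.5, 1.5))
                    edges.append(Edge(names[i], names[j], sign, weight))
                    touched.update((i, j))
        if edges and len(touched) == n:
            return RegulatoryNetwork(
                [Node(nm, "transcription_factor") for nm in names],
                edges,
                NodeAliasTable(),
            )
    raise RuntimeError(
        "could not generate a network where every node has an incident edge; "
        "increase edge_density"
    )


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def _scaled_adjacency(truth: RegulatoryNetwork, spectral_radius: float) -> np.ndarray:
    A = truth.to_adjacency().to_numpy()
    radius = float(np.max(np.abs(np.linalg.eigvals(A)))) if A.size else 0.0
    if radius > 0:
        A = A * (spectral_radius / radius)
        radius = spectral_radius
    if radius >= 1.0:
        raise ValueError("adjacency spectral radius >= 1 after scaling; no steady state")
    return A


def steady_state_expression(
    truth: RegulatoryNetwork,
    perturbations: np.ndarray,
    noise_sd: float,
    seed: int,
    spectral_radius: float = 0.8,
    clamp_zero: Sequence[tuple[int, int]] = (),
) -> np.ndarray:
    """Solve x = Aᵀx + u per sample; optionally clamp (gene, sample) to 0.

    ``perturbations`` is genes × samples; measurement noise is added after
    solving, except on clamped genes which stay exactly 0.
    """
    A = _scaled_adjacency(truth, spectral_radius)
    n, m = perturbations.shape
    rng = np.random.default_rng(seed)
    M = np.eye(n) - A.T
    clamped_by_sample: dict[int, set[int]] = {}
    for gene, sample in clamp_zero:
        clamped_by_sample.setdefault(sample, set()).add(gene)
    X = np.zeros((n, m))
    for s in range(m):
        clamped = clamped_by_sample.get(s, set())
        free = [i for i in range(n) if i not in clamped]
        Mf = M[np.ix_(free, free)]
        xf = np.linalg.solve(Mf, perturbations[free, s])
        X[free, s] = xf
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=(n, m))
        for s, genes in clamped_by_sample.items():
            for gene in genes:
                noise[gene, s] = 0.0
        X = X + noise
    return X


def _driver_indices(truth: RegulatoryNetwork, declared: Sequence[str]) -> list[int]:
    names = truth.node_names
    if declared:
        return [names.index(truth.aliases.canonicalize(d)) for d in declared]
    return [0]


def simulate_expression(truth: RegulatoryNetwork, config: GeneratorConfig) -> ExpressionMatrix:
    """Design-specific steady-state expression with sample metadata."""
    if not truth.nodes:
        raise ValueError("truth network is empty")
    names = truth.node_names
    n = len(names)
    rng = np.random.default_rng(config.seed + 1)
    noise_seed = int(rng.integers(0, 2**31 - 1))

    if config.design == "multifactorial":
        m = config.n_samples
        u = rng.normal(0.0, config.perturbation_sd, size=(n, m))
        X = steady_state_expression(
            truth, u, config.noise_sd, noise_seed, config.spectral_radius
        )
        meta = pd.DataFrame(
            {
                "study": config.study,
                "zone": "",
                "treatment": "",
                "replicate": np.arange(1, m + 1),
            }
        )
    elif config.design == "knockout":
        m = config.n_samples
        u = rng.normal(0.0, config.perturbation_sd, size=(n, m))
        clamp = [(s % n, s) for s in range(m)]
        for gene, s in clamp:
            u[gene, s] = 0.0
        X = steady_state_expression(
            truth, u, config.noise_sd, noise_seed, config.spectral_radius, clamp_zero=clamp
        )
        meta = pd.DataFrame(
            {
                "study": config.study,
                "zone": "",
                "treatment": [f"KO:{names[s % n]}" for s in range(m)],
                "replicate": [s // n + 1 for s in range(m)],
            }
        )
    elif config.design == "zones":
        if config.n_zones < 2 or config.n_zones > len(ZONE_NAMES):
            raise ValueError(f"n_zones must be in [2, {len(ZONE_NAMES)}]")
        zones = ZONE_NAMES[: config.n_zones]
        drivers = _driver_indices(truth, config.zone_drivers)
        m = config.n_zones * config.n_replicates
        u = rng.normal(0.0, config.perturbation_sd, size=(n, m))
        zone_col, rep_col = [], []
        levels = np.linspace(0.0, 1.0, config.n_zones)
        for s in range(m):
            z = s // config.n_replicates
            zone_col.append(zones[z])
            rep_col.append(s % config.n_replicates + 1)
        # drivers are clamped *at the level*, not at zero: solve with their
        # value fixed by substituting the level into the other equations
        A = _scaled_adjacency(truth, config.spectral_radius)
        M = np.eye(n) - A.T
        X = np.zeros((n, m))
        free = [i for i in range(n) if i not in set(drivers)]
        for s in range(m):
            z = s // config.n_replicates
            xd = np.zeros(n)
            for d in drivers:
                xd[d] = levels[z]
            rhs = u[free, s] + (A.T @ xd)[free]
            X[free, s] = np.linalg.solve(M[np.ix_(free, free)], rhs)
            for d in drivers:
                X[d, s] = levels[z]
        if config.noise_sd > 0:
            noise = np.random.default_rng(noise_seed).normal(0, config.noise_sd, (n, m))
            for d in drivers:
                noise[d, :] = 0.0
            X = X + noise
        meta = pd.DataFrame(
            {"study": config.study, "zone": zone_col, "treatment": "", "replicate": rep_col}
        )
    elif config.design == "treatment":
        m = config.n_samples
        targets = _driver_indices(truth, config.treatment_targets)
        u = rng.normal(0.0, config.perturbation_sd, size=(n, m))
        treated = [s >= m // 2 for s in range(m)]
        for s in range(m):
            if treated[s]:
                for t in targets:
                    u[t, s] += config.treatment_effect
        X = steady_state_expression(
            truth, u, config.noise_sd, noise_seed, config.spectral_radius
        )
        meta = pd.DataFrame(
            {
                "study": config.study,
                "zone": "",
                "treatment": ["treated" if t else "control" for t in treated],
                "replicate": [sum(treated[: s + 1]) if treated[s] else s + 1 for s in range(m)],
            }
        )
    else:  # pragma: no cover - guarded by GeneratorConfig
        raise ValueError(config.design)

    sample_ids = [f"{config.study}_s{i + 1:02d}" for i in range(X.shape[1])]
    meta.index = pd.Index(sample_ids)
    values = pd.DataFrame(X, index=names, columns=sample_ids)
    return ExpressionMatrix(values, meta)


def make_dataset(config: GeneratorConfig) -> SyntheticDataset:
    truth = generate_network(config)
    expr = simulate_expression(truth, config)
    return SyntheticDataset(truth, expr, config)


def growth_plate_study_emulation(
    truth: RegulatoryNetwork, noise_sd: float = 0.25, seed: int = 0
) -> ExpressionMatrix:
    """Five-study compendium shaped like the growth-plate microarray corpus:
    two treatment/control studies (12 and 15 samples), a four-zone study
    (8 samples), a three-zone study (12 samples) and an 18-sample
    zones-within-treatment explant-style study; 65 samples in total."""
    layouts = [
        GeneratorConfig(seed=seed + 11, design="treatment", n_samples=12, noise_sd=noise_sd,
                        study="study1"),
        GeneratorConfig(seed=seed + 12, design="zones", n_zones=4, n_replicates=2,
                        noise_sd=noise_sd, study="study2"),
        GeneratorConfig(seed=seed + 13, design="treatment", n_samples=15, noise_sd=noise_sd,
                        study="study3"),
        GeneratorConfig(seed=seed + 14, design="zones", n_zones=3, n_replicates=4,
                        noise_sd=noise_sd, study="study4"),
        GeneratorConfig(seed=seed + 15, design="zones", n_zones=3, n_replicates=6,
                        noise_sd=noise_sd, study="study5"),
    ]
    parts = [simulate_expression(truth, cfg) for cfg in layouts]
    values = pd.concat([p.values for p in parts], axis=1)
    meta = pd.concat([p.metadata for p in parts], axis=0)
    return ExpressionMatrix(values, meta)


# ---------------------------------------------------------------------------
# Packaged growth-plate fixture
# ---------------------------------------------------------------------------

def growth_plate_fixture() -> tuple[list[str], PriorMatrix]:
    """The 13 growth-plate transcription factors used for inference and the
    curated prior sign matrix over them (9 signed interactions)."""
    data = importlib.resources.files("chondronet") / "data"
    genes = [
        line.strip()
        for line in (data / "growth_plate_genes.txt").read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]
    import io

    prior_df = pd.read_csv(
        io.StringIO((data / "growth_plate_prior.tsv").read_text(encoding="utf-8")),
        sep="\t",
        index_col=0,
    )
    prior = PriorMatrix(list(prior_df.index), prior_df.to_numpy())
    if prior.node_order != genes:
        raise RuntimeError("packaged fixture files disagree on gene order")
    return genes, prior


def growth_plate_network() -> RegulatoryNetwork:
    """The 13 TF nodes with the prior's 9 signed interactions as edges."""
    _, prior = growth_plate_fixture()
    return prior.to_network()
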