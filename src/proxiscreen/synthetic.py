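"""Synthetic-data generators for every pipeline input.

Real inputs to this kind of screen — a curated interactome, drug–target
tables, MD trajectories, expression cohorts — are external resources.  The
generators here plant known structure in each input class so that every
analysis stage can be tested end-to-end against ground truth:

* scale-free-ish PPI networks with a disease-gene module and drugs whose
  targets sit at controlled network distance from it,
* Gaussian-fluctuation trajectories with planted per-residue amplitudes,
  inter-residue correlation blocks, or low-dimensional motion modes,
* two-group expression matrices with planted Cohen's d shifts.

All generators are fully deterministic given (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .expression import ExpressionMatrix
from .network import GeneSet, InteractionNetwork
from .proximity import DrugProfile
from .trajectory import AtomLabel, Trajectory

__all__ = [
    "DrugSpec",
    "NetworkScenario",
    "TrajectoryScenario",
    "ExpressionScenario",
    "make_network",
    "make_trajectory",
    "make_expression",
    "PLANTED_CLASSES",
]

PLANTED_CLASSES = ("proximal-weighted", "proximal-unweighted", "remote")


@dataclass
class DrugSpec:
    """One synthetic drug: id, planted proximity class, target count."""

    drug_id: str
    planted_class: str
    n_targets: int = 3

    def __post_init__(self) -> None:
        if self.planted_class not in PLANTED_CLASSES:
            raise ValueError(f"unknown planted class {self.planted_class!r}")
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")


@dataclass
class NetworkScenario:
    """Parameters of a planted-proximity network instance.

    The default graph (600 nodes, preferential attachment m=2) mimics the
    degree heterogeneity of a PPI interactome at desk scale, which is what
    makes the -ln(D+1) disease-gene weight consequential.  The disease
    module is a connected, peripheral node sample so that nodes three or
    more hops away exist for the "remote" drug class.
    """

    n_nodes: int = 600
    attachment: int = 2
    disease_module_size: int = 20
    drugs: Sequence[DrugSpec] = field(default_factory=lambda: default_drugs())
    model: str = "preferential_attachment"  # or "configuration"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.disease_module_size >= self.n_nodes:
            raise ValueError("disease module must be smaller than the network")
        if self.model not in ("preferential_attachment", "configuration"):
            raise ValueError(f"unknown network model {self.model!r}")


def default_drugs(n_per_class: int = 4, n_targets: int = 3) -> list[DrugSpec]:
    """A balanced drug panel: ``n_per_class`` drugs of each planted class."""
    out = []
    for cls in PLANTED_CLASSES:
        tag = {"proximal-weighted": "PW", "proximal-unweighted": "PU", "remote": "RM"}[cls]
        out.extend(DrugSpec(f"DRUG_{tag}{i:02d}", cls, n_targets) for i in range(n_per_class))
    return out


def _node_name(i: int) -> str:
    return f"G{i:04d}"


def _base_graph(scenario: NetworkScenario, rng: np.random.Generator) -> nx.Graph:
    graph_seed = int(rng.integers(0, 2**31 - 1))
    if scenario.model == "preferential_attachment":
        g = nx.barabasi_albert_graph(scenario.n_nodes, scenario.attachment, seed=graph_seed)
    else:
        # configuration-model alternative with a heavy-tailed degree sequence
        deg = np.minimum(
            rng.zipf(2.4, size=scenario.n_nodes) + scenario.attachment - 1,
            scenario.n_nodes // 4,
        )
        if deg.sum() % 2:
            deg[int(np.argmax(deg))] += 1
        g = nx.Graph(nx.configuration_model(deg.tolist(), seed=graph_seed))
        g.remove_edges_from(nx.selfloop_edges(g))
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        g = nx.convert_node_labels_to_integers(g)
    return nx.relabel_nodes(g, {i: _node_name(i) for i in g.nodes})


def _sample_disease_module(g: nx.Graph, size: int, rng: np.random.Generator) -> set[str]:
    """Connected node sample grown preferentially through low-degree nodes,
    keeping the module peripheral."""
    start = min(sorted(g.nodes), key=lambda n: (g.degree[n], rng.random()))
    module = {start}
    frontier = set(g.neighbors(start))
    while len(module) < size:
        if not frontier:
            raise ValueError("graph too fragmented to grow a connected disease module")
        candidates = sorted(frontier, key=lambda n: (g.degree[n], n))
        # pick among the lowest-degree frontier nodes with a little randomness
        k = min(3, len(candidates))
        pick = candidates[int(rng.integers(0, k))]
        module.add(pick)
        frontier |= set(g.neighbors(pick))
        frontier -= module
    return module


def make_network(
    scenario: NetworkScenario,
) -> tuple[InteractionNetwork, GeneSet, list[DrugProfile], pd.DataFrame]:
    """Generate a network, disease gene set, drug panel, and truth table.

    Planted classes:

    * ``proximal-weighted`` — targets are disease genes with degree >= 1, so
      every target term is 0 - ln(D+1) < 0 and the drug's distance is
      negative by construction;
    * ``proximal-unweighted`` — targets are non-disease first neighbours of
      the module (distance exactly 1 per target, no weight: small but >= 0);
    * ``remote`` — targets are >= 3 hops from every disease gene.

    Raises ``ValueError`` when a class has fewer eligible nodes than a drug
    requests.
    """
    rng = np.random.default_rng(scenario.seed)
    g = _base_graph(scenario, rng)
    module = _sample_disease_module(g, scenario.disease_module_size, rng)
    disease = GeneSet("synthetic-disease", module)
    net = InteractionNetwork(graph=g)
    dist = net.distances_from(module)

    pools: dict[str, list[str]] = {
        "proximal-weighted": sorted(n for n in module if g.degree[n] >= 1),
        "proximal-unweighted": sorted(n for n in g.nodes if n not in module and dist.get(n) == 1),
        "remote": sorted(n for n in g.nodes if dist.get(n, -1) >= 3),
    }
    drugs: list[DrugProfile] = []
    truth_rows = []
    for spec in scenario.drugs:
        pool = pools[spec.planted_class]
        if len(pool) < spec.n_targets:
            raise ValueError(
                f"scenario unrealizable: class {spec.planted_class!r} has "
                f"{len(pool)} eligible nodes, drug {spec.drug_id} needs {spec.n_targets}"
            )
        idx = rng.choice(len(pool), size=spec.n_targets, replace=False)
        targets = {pool[i] for i in idx}
        drugs.append(DrugProfile(spec.drug_id, targets))
        truth_rows.append({"drug_id": spec.drug_id, "planted_class": spec.planted_class,
                           "n_targets": spec.n_targets})
    truth = pd.DataFrame(truth_rows)
    return net, disease, drugs, truth


@dataclass
class TrajectoryScenario:
    """Parameters of a correlated Gaussian-fluctuation trajectory.

    ``sigma`` is the per-residue fluctuation amplitude in Å (scalar or one
    value per residue); ``blocks`` are ``(range_a, range_b, rho)`` triples of
    1-based inclusive residue ranges given correlation ``rho`` (a range
    paired with itself correlates residues within the segment, mirroring a
    concertedly moving stretch).  ``modes`` replaces the residue-wise model
    with a low-dimensional one: displacements along random orthonormal 3N
    directions with the listed variances (Å^2).  ``rotation`` adds a random
    global rigid motion per frame to exercise superposition.
    """

    n_residues: int = 100
    n_frames: int = 2000
    dt: float = 0.05  # ns
    sigma: float | Sequence[float] = 0.5
    blocks: Sequence[tuple[tuple[int, int], tuple[int, int], float]] = ()
    modes: Optional[Sequence[float]] = None
    rotation: bool = False
    seed: int = 0


def _helix_reference(n_residues: int) -> np.ndarray:
    i = np.arange(n_residues)
    return np.column_stack([3.8 * i, 1.5 * np.sin(i), 1.5 * np.cos(i)])


def _rigid_basis(ref: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 6 rigid-body modes (translations and
    infinitesimal rotations) of a reference structure, in R^(3N)."""
    n = ref.shape[0]
    centered = ref - ref.mean(axis=0)
    cols = []
    for k in range(3):
        v = np.zeros((n, 3))
        v[:, k] = 1.0
        cols.append(v.ravel())
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        cols.append(np.cross(np.broadcast_to(e, (n, 3)), centered).ravel())
    q, _ = np.linalg.qr(np.column_stack(cols))
    return q


def _residue_correlation(scenario: TrajectoryScenario) -> np.ndarray:
    n = scenario.n_residues
    C = np.eye(n)
    for (a_lo, a_hi), (b_lo, b_hi), rho in scenario.blocks:
        ia = np.arange(a_lo - 1, a_hi)
        ib = np.arange(b_lo - 1, b_hi)
        for i in ia:
            for j in ib:
                if i != j:
                    C[i, j] = C[j, i] = rho
    eig_min = float(np.linalg.eigvalsh(C).min())
    if eig_min < -1e-8:
        raise ValueError(
            f"correlation blocks yield a non-PSD covariance (min eigenvalue {eig_min:.3g}): "
            f"{list(scenario.blocks)}"
        )
    return C


def make_trajectory(scenario: TrajectoryScenario) -> Trajectory:
    """Sample a trajectory of one CA point per residue around a helical mean.

    Residue-wise model: per-axis displacements are correlated across
    residues by the planted block matrix and scaled to sigma/sqrt(3) per
    axis, so the per-residue RMSF equals sigma and the displacement-vector
    correlation of residues i, j equals the planted rho.
    """
    rng = np.random.default_rng(scenario.seed)
    n_res, n_frames = scenario.n_residues, scenario.n_frames
    ref = _helix_reference(n_res)
    if scenario.modes is not None:
        variances = np.asarray(scenario.modes, dtype=float)
        dim = 3 * n_res
        raw = rng.standard_normal((dim, variances.size))
        # internal motions carry no net translation/rotation, so mode
        # directions are drawn orthogonal to the rigid-body subspace; the
        # planted variance ratios then survive superposition unchanged
        rigid = _rigid_basis(ref)
        raw -= rigid @ (rigid.T @ raw)
        q, _ = np.linalg.qr(raw)
        amplitudes = rng.standard_normal((n_frames, variances.size)) * np.sqrt(variances)
        disp = (amplitudes @ q.T).reshape(n_frames, n_res, 3)
    else:
        sigma = np.broadcast_to(np.asarray(scenario.sigma, dtype=float), (n_res,)).copy()
        C = _residue_correlation(scenario)
        L = np.linalg.cholesky(C + 1e-10 * np.eye(n_res))
        disp = np.empty((n_frames, n_res, 3))
        for axis in range(3):
            z = rng.standard_normal((n_frames, n_res))
            disp[:, :, axis] = (z @ L.T) * (sigma / np.sqrt(3.0))
        # Internal fluctuations carry no net translation/rotation; project the
        # rigid-body modes out, then rescale so each residue's marginal
        # amplitude is exactly sigma (computed from the projected covariance,
        # not re-estimated from the sample).  This keeps the planted
        # amplitudes identifiable after least-squares superposition.
        rigid = _rigid_basis(ref)
        flat = disp.reshape(n_frames, -1)
        flat -= (flat @ rigid) @ rigid.T
        cov_w = C * np.outer(sigma, sigma) / 3.0
        full = np.kron(cov_w, np.eye(3))
        proj = full - rigid @ (rigid.T @ full)
        proj -= (proj @ rigid) @ rigid.T
        proj_var = np.diag(proj).reshape(n_res, 3).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(proj_var > 0, sigma / np.sqrt(proj_var), 0.0)
        disp = flat.reshape(n_frames, n_res, 3) * scale[None, :, None]
    coords = ref[None, :, :] + disp
    if scenario.rotation:
        for t in range(n_frames):
            rot = Rotation.random(rng=rng)
            shift = rng.uniform(-20, 20, size=3)
            coords[t] = rot.apply(coords[t]) + shift
    labels = [AtomLabel(i + 1, "CA") for i in range(n_res)]
    return Trajectory(labels, coords, scenario.dt)


@dataclass
class ExpressionScenario:
    """Parameters of a two-group expression matrix with planted effects.

    ``signal`` maps gene name (e.g. ``"GENE0003"``) to a planted Cohen's d;
    the case-group mean of that gene is shifted by d * noise_sd.  Defaults
    (10 vs 10 samples, unit log-scale noise) emulate a small patient/control
    cohort.
    """

    n_genes: int = 1000
    n_case: int = 10
    n_control: int = 10
    signal: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0


def gene_name(i: int) -> str:
    return f"GENE{i:04d}"


def make_expression(scenario: ExpressionScenario) -> ExpressionMatrix:
    """Gaussian genes x samples matrix with planted case-group shifts."""
    rng = np.random.default_rng(scenario.seed)
    genes = [gene_name(i) for i in range(scenario.n_genes)]
    unknown = set(scenario.signal) - set(genes)
    if unknown:
        raise ValueError(f"signal genes not in the matrix: {sorted(unknown)}")
    n_samples = scenario.n_case + scenario.n_control
    baseline = rng.normal(scenario.baseline_mean, scenario.baseline_sd, scenario.n_genes)
    values = baseline[:, None] + rng.normal(0.0, scenario.noise_sd,
                                            (scenario.n_genes, n_samples))
    case_cols = [f"case_{i:02d}" for i in range(scenario.n_case)]
    control_cols = [f"control_{i:02d}" for i in range(scenario.n_control)]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                      columns=case_cols + control_cols)
    for gene, d in scenario.signal.items():
        df.loc[gene, case_cols] += d * scenario.noise_sd
    groups = pd.Series(
        ["case"] * scenario.n_case + ["control"] * scenario.n_control,
        index=case_cols + control_cols,
    )
    return ExpressionMatrix(values=df, groups=groups)
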