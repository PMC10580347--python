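"""Network-proximity drug screening.

For a disease gene set *S* and a drug with target set *T*, the screen scores

    d(S, T) = (1/|T|) * sum over t in T of [ min over s in S of d(s, t) + w(t) ]

where d(s, t) is the unweighted shortest-path length on the PPI network and
w(t) = -ln(D_t + 1) when the target t is itself a disease gene of degree D_t,
else w(t) = 0.  The weight term is what makes negative distances possible:
a drug whose targets are high-degree disease genes scores below zero, and
drugs with negative distance are the selected candidates.

A size-matched random reference distribution (uniform node samples of the
same target count) provides a z-score alongside the raw selected statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .network import GeneSet, InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "DrugProfile",
    "ProximityResult",
    "target_weight",
    "drug_distance",
    "reference_distribution",
    "screen_drugs",
    "load_drug_targets",
    "results_to_frame",
]


@dataclass
class DrugProfile:
    """A drug's identifier and target gene list."""

    drug_id: str
    targets: set[str]
    mapped_targets: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.targets = set(self.targets)
        self.mapped_targets = set(self.mapped_targets)
        if not self.mapped_targets <= self.targets:
            raise ValueError(f"{self.drug_id}: mapped_targets must be a subset of targets")

    def map_to_network(self, net: InteractionNetwork) -> "DrugProfile":
        """Return a copy with ``mapped_targets`` restricted to network nodes."""
        mapped = {t for t in self.targets if net.has_node(t)}
        dropped = self.targets - mapped
        if dropped:
            logger.info("%s: %d target(s) absent from network dropped: %s",
                        self.drug_id, len(dropped), sorted(dropped))
        return DrugProfile(self.drug_id, self.targets, mapped)


@dataclass
class ProximityResult:
    """Per-drug proximity score with reference-distribution context."""

    drug_id: str
    distance: float
    n_targets: int
    n_targets_used: int
    reference_mean: float = math.nan
    reference_sd: float = math.nan
    z_score: float = math.nan
    selected: bool = False


def target_weight(degree: int, is_disease_gene: bool) -> float:
    """Weight of a drug target: ``-ln(degree + 1)`` for disease genes, else 0."""
    if degree < 0:
        raise ValueError(f"degree must be non-negative, got {degree}")
    if not is_disease_gene:
        return 0.0
    return -math.log(degree + 1)


def _disease_distance_map(net: InteractionNetwork, disease: GeneSet) -> tuple[set[str], dict[str, int]]:
    members = disease.intersect_network(net)
    if not members:
        raise ValueError(f"no member of gene set {disease.name!r} is in the network")
    return members, net.distances_from(members)


def drug_distance(
    net: InteractionNetwork,
    disease: GeneSet,
    drug: DrugProfile,
    *,
    _dist_map: dict[str, int] | None = None,
    _members: set[str] | None = None,
) -> float | None:
    """Weighted mean closest distance from the drug's targets to the disease set.

    Returns ``None`` (undefined) when the drug has no mapped target, or when
    every target is unreachable from all disease genes; the reason is logged.
    Targets unreachable from the whole disease set are dropped with a warning.
    """
    if _dist_map is None or _members is None:
        _members, _dist_map = _disease_distance_map(net, disease)
    if not drug.mapped_targets:
        logger.warning("%s: no targets mapped to the network; unscorable", drug.drug_id)
        return None
    terms = []
    for t in sorted(drug.mapped_targets):
        if t not in _dist_map:
            logger.warning("%s: target %s unreachable from every disease gene; dropped",
                           drug.drug_id, t)
            continue
        w = target_weight(net.degree(t), t in _members)
        terms.append(_dist_map[t] + w)
    if not terms:
        logger.warning("%s: all targets unreachable; unscorable", drug.drug_id)
        return None
    return float(np.mean(terms))


def _score_node_sample(
    net: InteractionNetwork,
    members: set[str],
    dist_map: dict[str, int],
    nodes: Sequence[str],
) -> float | None:
    terms = []
    for t in nodes:
        if t not in dist_map:
            continue
        terms.append(dist_map[t] + target_weight(net.degree(t), t in members))
    if not terms:
        return None
    return float(np.mean(terms))


def reference_distribution(
    net: InteractionNetwork,
    disease: GeneSet,
    n_targets: int,
    n_samples: int,
    seed: int,
    *,
    min_defined: int = 10,
    _dist_map: dict[str, int] | None = None,
    _members: set[str] | None = None,
) -> np.ndarray:
    """Null distances of size-matched random target sets.

    Each sample draws ``n_targets`` distinct nodes uniformly (no degree
    matching) and scores them exactly like a drug — a sampled node that is a
    disease gene receives the ``-ln(D+1)`` weight.  Deterministic for a fixed
    seed.  Samples whose score is undefined (all nodes unreachable) are
    omitted; having fewer than ``min_defined`` defined samples warns, zero is
    an error.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if net.n_nodes < n_targets:
        raise ValueError("network smaller than requested target-set size")
    if _dist_map is None or _members is None:
        _members, _dist_map = _disease_distance_map(net, disease)
    node_list = sorted(net.nodes)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_samples):
        idx = rng.choice(len(node_list), size=n_targets, replace=False)
        d = _score_node_sample(net, _members, _dist_map, [node_list[i] for i in idx])
        if d is not None:
            out.append(d)
    if not out:
        raise ValueError("reference distribution empty: every sample was undefined")
    if len(out) < min_defined:
        logger.warning("reference distribution has only %d defined samples", len(out))
    return np.asarray(out, dtype=float)


def screen_drugs(
    net: InteractionNetwork,
    disease: GeneSet,
    drugs: Iterable[DrugProfile],
    n_samples: int = 1000,
    seed: int = 0,
) -> tuple[list[ProximityResult], list[str]]:
    """Score every drug, attach size-matched reference z-scores, rank.

    Reference distributions are cached per mapped-target count, with a
    deterministic per-count seed so results do not depend on drug order.
    With ``n_samples == 0`` the reference/z fields stay NaN (degraded mode).

    Returns
    -------
    (results, unscorable)
        ``results`` sorted ascending by distance (ties broken by drug id);
        ``unscorable`` lists drug ids that could not be scored.
    """
    members, dist_map = _disease_distance_map(net, disease)
    mapped = [d.map_to_network(net) for d in drugs]
    if not any(d.mapped_targets for d in mapped):
        raise ValueError("no scorable drug: no drug has a target in the network")

    ref_cache: dict[int, tuple[float, float]] = {}

    def ref_stats(k: int) -> tuple[float, float]:
        if k not in ref_cache:
            sub_seed = int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))
            ref = reference_distribution(
                net, disease, k, n_samples, sub_seed,
                _dist_map=dist_map, _members=members,
            )
            ref_cache[k] = (float(ref.mean()), float(ref.std(ddof=1)))
        return ref_cache[k]

    results: list[ProximityResult] = []
    unscorable: list[str] = []
    for drug in mapped:
        dist = drug_distance(net, disease, drug, _dist_map=dist_map, _members=members)
        if dist is None:
            unscorable.append(drug.drug_id)
            continue
        res = ProximityResult(
            drug_id=drug.drug_id,
            distance=dist,
            n_targets=len(drug.targets),
            n_targets_used=len(drug.mapped_targets & set(dist_map)),
            selected=dist < 0,
        )
        if n_samples > 0:
            mu, sd = ref_stats(len(drug.mapped_targets))
            res.reference_mean = mu
            res.reference_sd = sd
            if sd > 0:
                res.z_score = (dist - mu) / sd
        results.append(res)
    results.sort(key=lambda r: (r.distance, r.drug_id))
    logger.info("screened %d drugs (%d unscorable), %d selected",
                len(results), len(unscorable), sum(r.selected for r in results))
    return results, unscorable


def load_drug_targets(path: Union[str, Path]) -> list[DrugProfile]:
    """Read a ``drug_id<TAB>target_symbol`` table into drug profiles."""
    df = pd.read_csv(path, sep="\t", header=None, names=["drug_id", "target"],
                     dtype=str, comment="#")
    profiles = [
        DrugProfile(drug_id=str(drug), targets=set(sub["target"]))
        for drug, sub in df.groupby("drug_id", sort=True)
    ]
    if not profiles:
        raise ValueError(f"no drug-target pairs in {path}")
    return profiles


def results_to_frame(results: Sequence[ProximityResult]) -> pd.DataFrame:
    """Tabulate screen results in rank order."""
    return pd.DataFrame(
        [
            {
                "drug_id": r.drug_id,
                "n_targets": r.n_targets,
                "n_targets_used": r.n_targets_used,
                "distance": r.distance,
                "ref_mean": r.reference_mean,
                "ref_sd": r.reference_sd,
                "z": r.z_score,
                "selected": r.selected,
            }
            for r in results
        ]
    )
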