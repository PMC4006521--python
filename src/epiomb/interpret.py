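"""Biological interpretation of scan output and power aggregation.

The best ensemble is a set of SNP pairs; its pair graph decomposes the finding
into independent interactions.  Pairs sharing SNPs merge into one connected
component — an inferred multi-locus interaction of order equal to the
component size — while disconnected components indicate genetic
heterogeneity: independent interactions responsible for different case
subgroups.

Against simulated ground truth, detection is graded as:

* ``"one"`` — some ensemble pair has both SNPs causative for the *same*
  disease component (at least one interaction recovered);
* ``"two"`` — two ensemble pairs without a common SNP, each lying within a
  *different* disease component's causative set (both independent
  interactions recovered; implies ``"one"``);
* ``"none"`` otherwise (including pairs that straddle components).

Power over replicate datasets is the fraction achieving each verdict, with
the mean number of output SNPs and correctly identified causative SNPs as
companion parsimony/recovery metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .omnibus import Ensemble, ScanResult, scan
from .simulate import DiseaseArchitecture, simulate_dataset

__all__ = [
    "InteractionGraph",
    "PowerResult",
    "interaction_components",
    "classify_detection",
    "count_metrics",
    "power_study",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InteractionGraph:
    """Pair graph of an ensemble and its connected components."""

    nodes: tuple[int, ...]
    edges: tuple[tuple[int, int], ...]
    components: tuple[frozenset[int], ...]

    @property
    def n_interactions(self) -> int:
        return len(self.components)


def interaction_components(ensemble: Ensemble) -> InteractionGraph:
    """Connected components of the ensemble's pair graph.

    A component of size m is reported as an m-locus interaction; the number
    of components is the inferred number of independent interactions.
    """
    if not ensemble.pairs:
        raise ValueError("ensemble is empty")
    g = nx.Graph()
    g.add_edges_from(ensemble.pairs)
    comps = tuple(
        sorted((frozenset(c) for c in nx.connected_components(g)), key=min)
    )
    return InteractionGraph(
        nodes=tuple(sorted(g.nodes)),
        edges=tuple((min(i, j), max(i, j)) for i, j in ensemble.pairs),
        components=comps,
    )


def classify_detection(
    graph: InteractionGraph | Ensemble, truth: DiseaseArchitecture
) -> str:
    """Grade a detection against the simulated disease architecture.

    A pair "recovers" disease component c when both its SNPs belong to
    component c's causative set.  Verdicts: ``"two"`` if distinct components
    are each recovered by some pair (the pairs are automatically disjoint
    because causative sets are), ``"one"`` if at least one component is
    recovered, else ``"none"``.
    """
    if truth is None:
        raise ValueError("ground truth is required")
    edges = graph.edges if isinstance(graph, InteractionGraph) else tuple(graph.pairs)
    comp_sets = truth.component_index_sets
    recovered: set[int] = set()
    for i, j in edges:
        for c, snps in enumerate(comp_sets):
            if i in snps and j in snps:
                recovered.add(c)
    if len(recovered) >= 2:
        return "two"
    if len(recovered) == 1:
        return "one"
    return "none"


def count_metrics(
    result: ScanResult, truth: DiseaseArchitecture
) -> tuple[int, int]:
    """(number of output SNPs, number of correctly identified causative SNPs).

    Both are 0 when no association was declared: output SNPs are only counted
    for declared detections.
    """
    if truth is None:
        raise ValueError("ground truth is required")
    if not result.detected or result.best_ensemble is None:
        return 0, 0
    nodes = set(result.best_ensemble.snps)
    causative = set(truth.causative_indices)
    return len(nodes), len(nodes & causative)


@dataclass
class PowerResult:
    """Detection power aggregated over replicate datasets of one scenario."""

    scenario_id: str
    n_datasets: int
    power_at_least_one: float
    power_two: float
    mean_output_snps: float
    mean_correct_causative_snps: float
    records: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.power_two <= self.power_at_least_one + 1e-12:
            raise ValueError("power_two cannot exceed power_at_least_one")


def power_study(
    arch: DiseaseArchitecture,
    n_datasets: int,
    n_cases: int,
    n_controls: int,
    t: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    perm_pair_cap: int | None = None,
) -> PowerResult:
    """Simulate, scan and grade ``n_datasets`` replicate datasets.

    Per-dataset seeds are derived from ``seed`` via independent seed
    sequences, so any single dataset can be regenerated in isolation.
    Failures in individual datasets are recorded (verdict ``"error"``) rather
    than aborting the study.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be at least 1")
    rows = []
    for d in range(n_datasets):
        child = np.random.default_rng(np.random.SeedSequence([seed, d]))
        sim_seed, scan_seed = (int(x) for x in child.integers(0, 2**31, size=2))
        try:
            ds = simulate_dataset(arch, n_cases, n_controls, seed=sim_seed)
            res = scan(
                ds, alpha=alpha, t=t, seed=scan_seed, perm_pair_cap=perm_pair_cap
            )
            if res.detected and res.best_ensemble is not None:
                verdict = classify_detection(res.best_ensemble, arch)
            else:
                verdict = "none"
            n_out, n_correct = count_metrics(res, arch)
            best = res.best_ensemble
            rows.append(
                {
                    "dataset": d, "sim_seed": sim_seed, "scan_seed": scan_seed,
                    "detected": res.detected, "verdict": verdict,
                    "n_output_snps": n_out, "n_correct_causative": n_correct,
                    "p_raw": best.p_raw if best else np.nan,
                    "p_global": best.p_global if best else np.nan,
                    "n_ensemble_pairs": len(best.pairs) if best else 0,
                }
            )
        except Exception:
            logger.exception("dataset %d failed", d)
            rows.append(
                {
                    "dataset": d, "sim_seed": sim_seed, "scan_seed": scan_seed,
                    "detected": False, "verdict": "error",
                    "n_output_snps": 0, "n_correct_causative": 0,
                    "p_raw": np.nan, "p_global": np.nan, "n_ensemble_pairs": 0,
                }
            )
    records = pd.DataFrame(rows)
    at_least_one = float(records["verdict"].isin(["one", "two"]).mean())
    two = float((records["verdict"] == "two").mean())
    return PowerResult(
        scenario_id=arch.scenario_id or "scenario",
        n_datasets=n_datasets,
        power_at_least_one=at_least_one,
        power_two=two,
        mean_output_snps=float(records["n_output_snps"].mean()),
        mean_correct_causative_snps=float(records["n_correct_causative"].mean()),
        records=records,
    )
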