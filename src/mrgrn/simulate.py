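"""Planted-truth synthetic data: a reference GRN with hub master regulators
and matching two-condition negative-binomial count data (plus qPCR Ct tables).

The generator emulates a two-group bulk RNA-seq design with 4 replicates
per condition. A small set of planted master-regulator TFs (i) form hubs
of the reference network via preferential attachment, (ii) regulate each
other pairwise (so they direct and are directed by other candidates), and
(iii) are up-shifted in the case condition together with their direct
targets. A fraction of the remaining TFs is forced below the expression
cutoff in the case condition to exercise contextual pruning. All draws
come from a single integer-seeded generator per operation, so outputs are
fully deterministic given the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix, EdgeRecord
from .network import RegulatoryNetwork, build_reference_network

__all__ = [
    "SyntheticScenario",
    "PlantedTruth",
    "simulate_reference_grn",
    "simulate_counts",
    "simulate_qpcr",
    "write_scenario_outputs",
]

# mean raw count assigned to TFs forced below the expression cutoff (tau=10)
LOW_TF_MEAN = 5.0
# planted MRs draw their out-degree at this multiple of targets_per_tf
MR_HUB_FACTOR = 3.0
# fraction of TF->target edges that activate (the rest repress), roughly the
# skew of curated regulatory databases; a mixed-sign cascade also keeps the
# simulated transcriptome compositionally balanced, as real ones are
ACTIVATION_FRACTION = 0.6
HOUSEKEEPING_GENE = "Gapdh"


@dataclass
class SyntheticScenario:
    """Full parameterization of the planted-truth generator.

    The negative binomial is parameterized as variance = mu + dispersion * mu^2.
    Effect sizes are applied multiplicatively to NB means in the case
    condition. Defaults mirror a 4-replicate two-condition design with 5
    planted master regulators at desk scale.
    """

    seed: int = 1
    n_tfs: int = 30
    n_targets: int = 300
    n_planted_mrs: int = 5
    targets_per_tf: float = 8.0
    n_replicates: int = 4
    baseline_mean: float = 200.0
    dispersion: float = 0.1
    mr_log2fc: float = 1.5
    cascade_log2fc: float = 2.0
    frac_low_expressed_tfs: float = 0.2
    tissue: str = "colon"

    def __post_init__(self) -> None:
        if self.n_planted_mrs > self.n_tfs:
            raise ValueError("n_planted_mrs must not exceed n_tfs")
        for name in ("n_tfs", "n_targets", "n_planted_mrs", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.targets_per_tf <= 0:
            raise ValueError("targets_per_tf must be positive")
        if not 0 <= self.frac_low_expressed_tfs <= 1:
            raise ValueError("frac_low_expressed_tfs must lie in [0, 1]")
        if self.targets_per_tf > self.n_targets:
            raise ValueError(
                "targets_per_tf exceeds the target pool: no simple edge set exists"
            )
        if MR_HUB_FACTOR * self.targets_per_tf > self.n_targets:
            raise ValueError(
                "hub out-degree would exceed the target pool; "
                "increase n_targets or lower targets_per_tf"
            )

    @property
    def tf_symbols(self) -> list[str]:
        return [f"TF{i:03d}" for i in range(1, self.n_tfs + 1)]

    @property
    def target_symbols(self) -> list[str]:
        return [f"G{i:03d}" for i in range(1, self.n_targets + 1)]


@dataclass
class PlantedTruth:
    """What the generator planted, for downstream recovery checks."""

    planted_mrs: set[str]
    de_genes_expected: set[str]
    reference_edges: list[EdgeRecord]
    low_expressed_tfs: set[str] = field(default_factory=set)
    mr_log2fc: float = 1.5


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def simulate_reference_grn(
    scenario: SyntheticScenario,
) -> tuple[RegulatoryNetwork, PlantedTruth]:
    """Build the planted reference network.

    Each TF regulates a random target set drawn by preferential attachment
    (targets are weighted by 1 + current in-degree, so popular targets get
    shared between TFs). Planted MRs draw a 3x larger out-degree, making
    them hubs, and additionally regulate each other pairwise.
    """
    rng = _rng(scenario.seed, 0)
    tfs = scenario.tf_symbols
    targets = scenario.target_symbols
    planted = {str(t) for t in rng.choice(tfs, size=scenario.n_planted_mrs, replace=False)}
    n_low = int(round(scenario.frac_low_expressed_tfs * scenario.n_tfs))
    non_mr = [t for t in tfs if t not in planted]
    n_low = min(n_low, len(non_mr))
    low_tfs = (
        {str(t) for t in rng.choice(non_mr, size=n_low, replace=False)}
        if n_low
        else set()
    )

    in_deg = {t: 0 for t in targets}
    edges: list[EdgeRecord] = []
    target_arr = np.array(targets)
    for tf in tfs:
        mean_k = scenario.targets_per_tf * (
            MR_HUB_FACTOR if tf in planted else 1.0
        )
        k = max(1, int(rng.poisson(mean_k)))
        k = min(k, scenario.n_targets)
        weights = np.array([1.0 + in_deg[t] for t in targets])
        weights /= weights.sum()
        chosen = rng.choice(target_arr, size=k, replace=False, p=weights)
        for tgt in chosen:
            in_deg[tgt] += 1
            mode = (
                "activation"
                if rng.random() < ACTIVATION_FRACTION
                else "repression"
            )
            edges.append(
                EdgeRecord(tf, str(tgt), mode=mode, sources=frozenset({"synthetic"}))
            )
    for mr_a in sorted(planted):
        for mr_b in sorted(planted):
            if mr_a != mr_b:
                edges.append(
                    EdgeRecord(
                        mr_a, mr_b, mode="activation", sources=frozenset({"synthetic"})
                    )
                )
    net = build_reference_network([edges])
    cascade = {
        v for mr in planted for v in net.graph.successors(mr) if v not in planted
    }
    de_expected = planted | cascade | low_tfs
    truth = PlantedTruth(
        planted_mrs=planted,
        de_genes_expected=de_expected,
        reference_edges=edges,
        low_expressed_tfs=low_tfs,
        mr_log2fc=scenario.mr_log2fc,
    )
    return net, truth


def _cascade_signs(truth: PlantedTruth) -> dict[str, int]:
    """Net regulation sign per direct non-MR target of the planted MRs.

    +1 if the activating planted-MR edges into the target are at least as
    many as the repressing ones, else -1 (ties favor activation).
    """
    votes: dict[str, int] = {}
    planted = truth.planted_mrs
    for rec in truth.reference_edges:
        if rec.regulator in planted and rec.target not in planted:
            votes[rec.target] = votes.get(rec.target, 0) + (
                -1 if rec.mode == "repression" else 1
            )
    return {t: (1 if v >= 0 else -1) for t, v in votes.items()}


def _case_means(scenario: SyntheticScenario, truth: PlantedTruth) -> pd.Series:
    genes = scenario.tf_symbols + scenario.target_symbols
    mu = pd.Series(scenario.baseline_mean, index=genes, dtype=float)
    mu[sorted(truth.planted_mrs)] = scenario.baseline_mean * 2.0**scenario.mr_log2fc
    for tgt, sign in sorted(_cascade_signs(truth).items()):
        if tgt in mu.index:
            mu[tgt] = scenario.baseline_mean * 2.0 ** (sign * scenario.cascade_log2fc)
    mu[sorted(truth.low_expressed_tfs)] = LOW_TF_MEAN
    return mu


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    # NB with variance mu + alpha mu^2: shape r = 1/alpha, p = r / (r + mu)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_counts(scenario: SyntheticScenario, truth: PlantedTruth) -> CountMatrix:
    """Draw the two-condition count matrix implied by the planted truth.

    Control samples draw every gene at the baseline NB mean; case samples
    shift planted MRs by mr_log2fc, their direct non-MR targets by
    cascade_log2fc, and the designated low-expression TFs down to a mean
    below the contextualization cutoff.
    """
    if not truth.planted_mrs <= set(scenario.tf_symbols):
        raise ValueError("planted truth is inconsistent with the scenario's TF pool")
    rng = _rng(scenario.seed, 1)
    genes = scenario.tf_symbols + scenario.target_symbols
    mu_ctrl = np.full(len(genes), scenario.baseline_mean)
    mu_case = _case_means(scenario, truth).loc[genes].to_numpy()
    n = scenario.n_replicates
    cols = {}
    sample_rows = []
    for i in range(1, n + 1):
        sid = f"control_{i}"
        cols[sid] = _nb_draw(rng, mu_ctrl, scenario.dispersion)
        sample_rows.append((sid, scenario.tissue, "control", "B1"))
    for i in range(1, n + 1):
        sid = f"case_{i}"
        cols[sid] = _nb_draw(rng, mu_case, scenario.dispersion)
        sample_rows.append((sid, scenario.tissue, "case", "B1"))
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"), dtype=np.int64)
    meta = pd.DataFrame(
        sample_rows, columns=["sample_id", "tissue", "condition", "batch"]
    ).set_index("sample_id")
    return CountMatrix(counts, meta)


def simulate_qpcr(
    truth: PlantedTruth,
    n_control: int = 4,
    n_case: int = 3,
    seed: int = 1,
    noise_sd: float = 0.25,
    housekeeping_ct: float = 20.0,
    target_ct: float = 25.0,
) -> pd.DataFrame:
    """Per-animal Ct values for each planted MR plus the housekeeping gene.

    Case animals' target Ct is reduced by mr_log2fc cycles (one PCR cycle
    per doubling) with Gaussian noise of sd ``noise_sd``; at noise 0 the
    ddCt readout recovers the planted fold change exactly.
    """
    if n_control < 2 or n_case < 2:
        raise ValueError("need at least 2 animals per group")
    rng = _rng(seed, 2)
    animals = [("control", f"ctrl_m{i}") for i in range(1, n_control + 1)]
    animals += [("case", f"case_m{i}") for i in range(1, n_case + 1)]
    rows = []
    for group, animal in animals:
        rows.append(
            {
                "animal_id": animal,
                "group": group,
                "gene": HOUSEKEEPING_GENE,
                "ct": housekeeping_ct + rng.normal(0.0, noise_sd) if noise_sd else housekeeping_ct,
            }
        )
        for gene in sorted(truth.planted_mrs):
            base = target_ct - (truth.mr_log2fc if group == "case" else 0.0)
            rows.append(
                {
                    "animal_id": animal,
                    "group": group,
                    "gene": gene,
                    "ct": base + rng.normal(0.0, noise_sd) if noise_sd else base,
                }
            )
    return pd.DataFrame(rows, columns=["animal_id", "group", "gene", "ct"])


def write_scenario_outputs(scenario: SyntheticScenario, outdir: str | Path) -> dict:
    """Materialize one scenario as the pipeline's on-disk inputs.

    Writes counts.tsv, meta.tsv, edges.tsv (generic3col), qpcr.tsv,
    truth.json and scenario.json; returns the path map.
    """
    import json

    from .io import write_count_matrix, write_edge_list

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net, truth = simulate_reference_grn(scenario)
    cm = simulate_counts(scenario, truth)
    qpcr = simulate_qpcr(truth, seed=scenario.seed, noise_sd=0.25)
    paths = {
        "counts": outdir / "counts.tsv",
        "meta": outdir / "meta.tsv",
        "edges": outdir / "edges.tsv",
        "qpcr": outdir / "qpcr.tsv",
        "truth": outdir / "truth.json",
        "scenario": outdir / "scenario.json",
    }
    write_count_matrix(cm, paths["counts"], paths["meta"])
    write_edge_list(truth.reference_edges, paths["edges"])
    qpcr.to_csv(paths["qpcr"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "planted_mrs": sorted(truth.planted_mrs),
                "de_genes_expected": sorted(truth.de_genes_expected),
                "low_expressed_tfs": sorted(truth.low_expressed_tfs),
                "mr_log2fc": truth.mr_log2fc,
                "n_reference_edges": len(truth.reference_edges),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    with open(paths["scenario"], "w") as fh:
        json.dump(asdict(scenario), fh, indent=2, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
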