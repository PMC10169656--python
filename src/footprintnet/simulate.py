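"""Synthetic two-genotype, two-treatment (phospho)proteome benchmark.

Emulates the study design the pipeline targets: two FLT3-ITD genotype
contexts (``ITD-JMD``, ``ITD-TKD``), a control and a treated arm (e.g.
Ara-C exposure), at least three replicates, a signed causal prior network
ending in a phenotype sink (``DNA_damage``), regulons for kinases,
phosphatases and transcription factors, regulatory phosphosites, and
log2-intensity matrices in which a known set of active regulators drives
additive signed shifts on their targets.  Because the ground truth is
explicit, every downstream stage (differential statistics, footprint
inference, network modelling) can be benchmarked for sign recovery.

The generative model for the treated-minus-control expectation of a feature
is linear and additive: each active regulator R with signed activity a_R
adds ``a_R * regulon_sign(R, target)`` to every one of its targets, and
``a_R * effect`` to each of its own regulatory sites; everything else has
expectation zero.  Replicate values are the expectation plus iid Gaussian
noise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .activity import Regulon, RegulonSet
from .io import OmicsMatrix, write_matrix, write_network_tsv, write_sif
from .network import PriorNetwork

logger = logging.getLogger(__name__)

PHENOTYPE_NODE = "DNA_damage"
DEFAULT_GENOTYPES = ("ITD-JMD", "ITD-TKD")
# class imbalance mirroring a realistic signaling proteome: kinases dominate
# regulon-bearing entities, phosphatases are rare
DEFAULT_CLASS_PROPORTIONS = {"kinase": 0.35, "phosphatase": 0.05, "tf": 0.15, "other": 0.45}
DEFAULT_NOISE_SD = 0.25
BASELINE_MEAN = 25.0  # log2 MS intensity scale
BASELINE_SD = 2.0


@dataclass(frozen=True)
class GroundTruth:
    """The regulator activities a simulation encodes (and inference must recover).

    ``active_regulators`` maps regulator -> signed activity (nonzero real;
    sign = direction, magnitude = log2 shift per target).
    """

    active_regulators: Mapping[str, float]
    phenotype_node: str = PHENOTYPE_NODE
    phenotype_direction: int = 1

    def __post_init__(self) -> None:
        for reg, act in self.active_regulators.items():
            if act == 0:
                raise ValueError(f"active regulator {reg!r} must have nonzero activity")
        if self.phenotype_direction not in (-1, 1):
            raise ValueError("phenotype_direction must be +1 or -1")

    def signs(self) -> dict[str, int]:
        return {r: int(np.sign(a)) for r, a in self.active_regulators.items()}

    def to_dict(self) -> dict:
        return {
            "active_regulators": {r: float(a) for r, a in
                                  sorted(self.active_regulators.items())},
            "phenotype_node": self.phenotype_node,
            "phenotype_direction": self.phenotype_direction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(dict(d["active_regulators"]), d["phenotype_node"],
                   int(d["phenotype_direction"]))


@dataclass
class SyntheticExperiment:
    """A complete simulated study: matrices, prior knowledge and ground truth."""

    proteome: OmicsMatrix
    phospho: OmicsMatrix
    network: PriorNetwork
    regulons: RegulonSet
    reg_sites: pd.DataFrame
    truth: dict[str, GroundTruth]  # genotype -> truth
    seed: int

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.truth)


def generate_prior_network(
    n_nodes: int,
    mean_out_degree: float = 3.0,
    frac_inhibitory: float = 0.25,
    seed: int = 0,
    class_proportions: Mapping[str, float] | None = None,
    phenotype: str = PHENOTYPE_NODE,
) -> PriorNetwork:
    """Random signed causal network over ``n_nodes - 1`` signaling nodes plus
    one phenotype sink.

    Each signaling node draws its out-neighbours uniformly (a Binomial number
    with mean ``mean_out_degree``) from all other nodes including the
    phenotype; each edge is inhibitory with probability ``frac_inhibitory``.
    The phenotype is guaranteed at least one incoming edge and never has
    outgoing ones.  Node classes (kinase / phosphatase / tf / other) are
    drawn from ``class_proportions``.
    """
    if n_nodes < 2:
        raise ValueError(f"n_nodes must be >= 2, got {n_nodes}")
    if not 0 <= frac_inhibitory <= 1:
        raise ValueError("frac_inhibitory must lie in [0, 1]")
    props = dict(class_proportions or DEFAULT_CLASS_PROPORTIONS)
    classes = sorted(props)
    weights = np.array([props[c] for c in classes], dtype=float)
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)

    n_signaling = n_nodes - 1
    width = max(4, len(str(n_signaling)))
    names = [f"P{i:0{width}d}" for i in range(1, n_signaling + 1)]
    net = PriorNetwork()
    drawn = rng.choice(len(classes), size=n_signaling, p=weights)
    for name, ci in zip(names, drawn):
        net.add_node(name, node_class=classes[ci])
    net.add_node(phenotype, node_class="phenotype", phenotype=True)

    all_nodes = names + [phenotype]
    p_edge = min(1.0, mean_out_degree / (n_nodes - 1))
    for u in names:
        candidates = [v for v in all_nodes if v != u]
        k = rng.binomial(len(candidates), p_edge)
        if k == 0:
            continue
        targets = rng.choice(len(candidates), size=k, replace=False)
        for ti in sorted(targets):
            v = candidates[ti]
            sign = -1 if rng.random() < frac_inhibitory else 1
            net.add_edge(u, v, sign, mechanism="simulated")
    if net.graph.in_degree(phenotype) == 0:
        u = names[int(rng.integers(len(names)))]
        sign = -1 if rng.random() < frac_inhibitory else 1
        net.add_edge(u, phenotype, sign, mechanism="simulated")
    return net


def _draw_site(rng: np.random.Generator, host: str, used: set[str]) -> str:
    """A fresh phosphosite ID on ``host`` (S/T/Y weighted like real data)."""
    while True:
        residue = rng.choice(["S", "T", "Y"], p=[0.8, 0.15, 0.05])
        position = int(rng.integers(1, 1000))
        site = f"{host}_{residue}{position}"
        if site not in used:
            used.add(site)
            return site


def generate_regulons(
    network: PriorNetwork,
    targets_per_regulator: int = 5,
    seed: int = 0,
    n_kinase_regulators: int | None = None,
) -> tuple[RegulonSet, pd.DataFrame]:
    """Signed regulons plus regulatory-site annotations for a prior network.

    Kinases and phosphatases receive ``targets_per_regulator`` phosphosite
    targets (globally unique sites on random signaling proteins); the stored
    sign is the expected direction of the site's change when the regulator is
    active.  TFs receive protein-level targets.  Every signaling node
    additionally carries 0-2 regulatory sites on itself annotated as
    activating (+1) or inhibiting (-1).  ``n_kinase_regulators`` restricts
    how many kinase/phosphatase nodes are given regulons (all by default).
    """
    rng = np.random.default_rng(seed)
    signaling = [n for n in network.nodes if not network.is_phenotype(n)]
    if not signaling:
        raise ValueError("network has no signaling nodes")
    kin_phos = [n for n in signaling if network.node_class(n) in ("kinase", "phosphatase")]
    tfs = [n for n in signaling if network.node_class(n) == "tf"]
    if not kin_phos and not tfs:
        raise ValueError("network has no kinase, phosphatase or TF node")
    if n_kinase_regulators is not None and n_kinase_regulators < len(kin_phos):
        chosen = rng.choice(len(kin_phos), size=n_kinase_regulators, replace=False)
        kin_phos = [kin_phos[i] for i in sorted(chosen)]

    used_sites: set[str] = set()
    regulons: dict[str, Regulon] = {}
    for reg in kin_phos:
        targets = []
        for _ in range(targets_per_regulator):
            host = signaling[int(rng.integers(len(signaling)))]
            site = _draw_site(rng, host, used_sites)
            sign = 1 if rng.random() < 0.9 else -1
            targets.append((site, sign))
        regulons[reg] = Regulon(reg, network.node_class(reg), tuple(targets))
    for reg in tfs:
        k = min(targets_per_regulator, len(signaling) - 1)
        pool = [n for n in signaling if n != reg]
        idx = rng.choice(len(pool), size=k, replace=False)
        targets = tuple(
            (pool[i], 1 if rng.random() < 0.7 else -1) for i in sorted(idx)
        )
        regulons[reg] = Regulon(reg, "tf", targets)

    site_rows = []
    for node in signaling:
        for _ in range(int(rng.integers(0, 3))):
            site = _draw_site(rng, node, used_sites)
            effect = 1 if rng.random() < 0.6 else -1
            site_rows.append({"site": site, "protein": node, "effect": effect})
    reg_sites = pd.DataFrame(site_rows, columns=["site", "protein", "effect"])
    reg_sites = reg_sites.sort_values(["protein", "site"]).reset_index(drop=True)
    return RegulonSet(regulons), reg_sites


def expected_shifts(
    regulons: RegulonSet, reg_sites: pd.DataFrame, truth: GroundTruth
) -> tuple[dict[str, float], dict[str, float]]:
    """Noise-free treated-minus-control expectations implied by the truth.

    Returns (phospho_shift_by_site, proteome_shift_by_protein).  Multiple
    active regulators hitting one target combine additively.  Active
    regulators' own abundance shifts by their activity (proteome layer), and
    their own regulatory sites move according to the site's annotated effect.
    """
    phospho: dict[str, float] = {}
    proteome: dict[str, float] = {}
    for reg, activity in truth.active_regulators.items():
        if reg in regulons:
            regulon = regulons[reg]
            for target, sign in regulon.targets:
                if regulon.klass == "tf":
                    proteome[target] = proteome.get(target, 0.0) + activity * sign
                else:
                    phospho[target] = phospho.get(target, 0.0) + activity * sign
        proteome[reg] = proteome.get(reg, 0.0) + activity
        own = reg_sites[reg_sites["protein"] == reg]
        for _, row in own.iterrows():
            phospho[row["site"]] = phospho.get(row["site"], 0.0) + activity * int(row["effect"])
    return phospho, proteome


def simulate_experiment(
    network: PriorNetwork,
    regulons: RegulonSet,
    truth: GroundTruth | Mapping[str, GroundTruth],
    n_replicates: int = 3,
    noise_sd: float = DEFAULT_NOISE_SD,
    loc_prob_low_fraction: float = 0.1,
    seed: int = 0,
    reg_sites: pd.DataFrame | None = None,
    genotypes: tuple[str, ...] = DEFAULT_GENOTYPES,
    n_background_sites: int = 200,
    n_background_proteins: int = 100,
) -> SyntheticExperiment:
    """Simulate log2 intensity matrices for a two-arm design with known truth.

    ``truth`` may be one :class:`GroundTruth` (applied to every genotype) or
    a mapping genotype -> truth (context-specific signaling).  Control
    columns fluctuate around each feature's baseline; treated columns add
    the genotype's expected shift.  A ``loc_prob_low_fraction`` Bernoulli
    share of phosphosites receives a localization probability below the
    class I threshold.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0 <= loc_prob_low_fraction <= 1:
        raise ValueError("loc_prob_low_fraction must lie in [0, 1]")
    if isinstance(truth, GroundTruth):
        truth_by_genotype = {g: truth for g in genotypes}
    else:
        truth_by_genotype = dict(truth)
        genotypes = tuple(sorted(truth_by_genotype))
    if reg_sites is None:
        reg_sites = pd.DataFrame(columns=["site", "protein", "effect"])
    for g, t in truth_by_genotype.items():
        missing = [r for r in t.active_regulators if r not in network]
        if missing:
            raise ValueError(f"{g}: active regulators absent from network: {missing}")

    rng = np.random.default_rng(seed)
    signaling = [n for n in network.nodes if not network.is_phenotype(n)]

    phospho_features = sorted(
        {t for _, reg in regulons.items() if reg.klass != "tf" for t, _ in reg.targets}
        | set(reg_sites["site"])
        | {f"BGP{i:04d}_S{100 + i}" for i in range(1, n_background_sites + 1)}
    )
    proteome_features = sorted(
        set(signaling)
        | {t for _, reg in regulons.items() if reg.klass == "tf" for t, _ in reg.targets}
        | {f"XPR{i:04d}" for i in range(1, n_background_proteins + 1)}
    )

    shift_phos = {g: expected_shifts(regulons, reg_sites, t)[0]
                  for g, t in truth_by_genotype.items()}
    shift_prot = {g: expected_shifts(regulons, reg_sites, t)[1]
                  for g, t in truth_by_genotype.items()}

    def _matrix(features: list[str], shifts: dict[str, dict[str, float]]) -> pd.DataFrame:
        baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=len(features))
        cols: dict[str, np.ndarray] = {}
        for genotype in genotypes:
            for treatment in ("control", "treated"):
                for rep in range(1, n_replicates + 1):
                    mu = baseline.copy()
                    if treatment == "treated":
                        sh = shifts[genotype]
                        mu = mu + np.array([sh.get(f, 0.0) for f in features])
                    noise = rng.normal(0.0, noise_sd, size=len(features)) if noise_sd > 0 else 0.0
                    cols[f"{genotype}.{treatment}.r{rep}"] = mu + noise
        return pd.DataFrame(cols, index=pd.Index(features, name="feature"))

    prot_values = _matrix(proteome_features, shift_prot)
    phos_values = _matrix(phospho_features, shift_phos)
    low = rng.random(len(phospho_features)) < loc_prob_low_fraction
    loc_prob = pd.Series(
        np.where(low, rng.uniform(0.3, 0.7499, len(phospho_features)),
                 rng.uniform(0.75, 1.0, len(phospho_features))),
        index=phos_values.index,
        name="loc_prob",
    )
    return SyntheticExperiment(
        proteome=OmicsMatrix(prot_values, "proteome"),
        phospho=OmicsMatrix(phos_values, "phospho", loc_prob),
        network=network,
        regulons=regulons,
        reg_sites=reg_sites,
        truth=dict(truth_by_genotype),
        seed=seed,
    )


def choose_truth(
    regulons: RegulonSet,
    n_active: int,
    magnitude: float = 1.5,
    seed: int = 0,
    classes: tuple[str, ...] = ("kinase", "phosphatase"),
    phenotype: str = PHENOTYPE_NODE,
    phenotype_direction: int = 1,
) -> GroundTruth:
    """Pick ``n_active`` regulators of the given classes and assign random signs."""
    pool = sorted(r for r, reg in regulons.items() if reg.klass in classes)
    if n_active > len(pool):
        raise ValueError(f"cannot pick {n_active} active regulators from {len(pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n_active, replace=False)
    active = {
        pool[i]: float(magnitude) * (1 if rng.random() < 0.5 else -1)
        for i in sorted(idx)
    }
    return GroundTruth(active, phenotype, phenotype_direction)


def standard_benchmark(
    seed: int = 42,
    noise_sd: float = DEFAULT_NOISE_SD,
    n_nodes: int = 200,
    n_regulators: int = 20,
    n_active: int = 8,
    magnitude: float = 1.5,
    targets_per_regulator: int = 5,
    n_replicates: int = 3,
    genotype: str = "ITD-JMD",
) -> tuple[SyntheticExperiment, GroundTruth]:
    """The package's reference parameter-recovery benchmark.

    One genotype context over a 200-node prior with 20 regulon-bearing
    kinase/phosphatase regulators, 8 of them active at |activity| = 1.5 with
    5 substrate sites each, 3 replicates per arm and replicate noise
    sd 0.25 — a solvable but noisy instance on which footprint inference is
    expected to recover essentially every active regulator's sign.
    """
    net = generate_prior_network(n_nodes, 3.0, 0.25, seed=seed)
    regulons, reg_sites = generate_regulons(
        net, targets_per_regulator, seed=seed + 1, n_kinase_regulators=n_regulators
    )
    truth = choose_truth(regulons, n_active, magnitude, seed=seed + 2)
    exp = simulate_experiment(
        net, regulons, truth, n_replicates, noise_sd, 0.1, seed=seed + 3,
        reg_sites=reg_sites, genotypes=(genotype,),
    )
    return exp, truth


def write_experiment(exp: SyntheticExperiment, out_dir: str | Path) -> dict[str, Path]:
    """Export a simulated study as the pipeline's plain-text input bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteome": out / "proteome.tsv",
        "phospho": out / "phospho.tsv",
        "network": out / "network.tsv",
        "sif": out / "network.sif",
        "regulons": out / "regulons.tsv",
        "reg_sites": out / "reg_sites.tsv",
        "truth": out / "truth.json",
        "node_classes": out / "node_classes.tsv",
    }
    write_matrix(exp.proteome, paths["proteome"])
    write_matrix(exp.phospho, paths["phospho"])
    write_network_tsv(exp.network, paths["network"])
    write_sif(exp.network.edge_list(), paths["sif"])
    exp.regulons.to_frame().to_csv(paths["regulons"], sep="\t", index=False,
                                   lineterminator="\n")
    exp.reg_sites.to_csv(paths["reg_sites"], sep="\t", index=False, lineterminator="\n")
    pd.DataFrame(
        [{"node": n, "node_class": exp.network.node_class(n)} for n in exp.network.nodes],
        columns=["node", "node_class"],
    ).to_csv(paths["node_classes"], sep="\t", index=False, lineterminator="\n")
    truth_payload = {g: t.to_dict() for g, t in sorted(exp.truth.items())}
    paths["truth"].write_text(json.dumps(truth_payload, indent=2, sort_keys=True) + "\n")
    return paths
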