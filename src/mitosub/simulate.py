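"""Synthetic trees, genomes, covariates and substitution histories.

The generator is the in-silico twin of the fitted model: substitution
counts on a branch are Poisson with log-rate equal to a linear combination
of the parent-node state's factor values plus log branch duration,
optionally multiplied by a per-site Gamma variate (shape ``gamma_shape``,
mean 1), which makes the marginal counts negative binomial.  Events are
placed at branch ends and the derived base is drawn with fixed
transition:transversion odds ``1 : tv_ts_ratio`` (the two transversion
partners split their share evenly), matching the estimator's convention
that a branch's whole duration is spent in the parent state.

Trees are random coalescent-style topologies with tips at time 0: while
``k`` lineages remain, the waiting time to the next merge is exponential
with mean ``2 * branch_time_mean / k``, which makes the expected total
tree length equal ``branch_time_mean`` times the number of branches.

Everything is reproducible from one integer seed, and the generator can
emit the exact ingest formats (branch TSV, root FASTA, annotation TSV,
covariate TSV) plus a truth log of every simulated event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .branch_time import NodeTimes
from .genetic_code import BASES
from .genome import (
    AnnotatedGenome,
    Region,
    write_annotation,
    write_covariates,
    write_reference,
)
from .phylo import Node, PhyloTree, Substitution, write_branch_table

_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class TrueModel:
    """Ground-truth log-linear rate model for the simulator.

    ``effects`` maps factor name -> level -> coefficient (reference levels
    implicitly 0); ``covariate_effects`` maps covariate column ->
    coefficient.  ``gamma_shape=None`` gives a pure Poisson process;
    a finite shape multiplies every site's rate by an independent
    Gamma(shape, 1/shape) variate.

    Interactions with the codon position are expressed with a compound
    factor key ``"codon_position*<factor>"`` whose levels are
    ``"<position>:<level>"``, e.g. ``{"codon_position*right_neighbor":
    {"3:G": 1.0}}`` raises the rate of third-position sites with a G to the
    right.  Such truths make by-position partitioning genuinely optimal.
    """

    intercept: float = -4.0
    effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    tv_ts_ratio: float = 0.05
    gamma_shape: float | None = None


@dataclass
class SimulationConfig:
    seed: int = 0
    n_tips: int = 100
    branch_time_mean: float = 1.0
    true_model: TrueModel = field(default_factory=TrueModel)


def simulate_tree(
    n_tips: int, branch_time_mean: float, rng: np.random.Generator
) -> PhyloTree:
    """Random rooted binary tree with tips at time 0 and stored node times."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    nodes: dict[str, Node] = {}
    active: list[str] = []
    for i in range(n_tips):
        nid = f"T{i}"
        nodes[nid] = Node(nid, is_tip=True, time=0.0)
        active.append(nid)
    t = 0.0
    counter = 0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 * branch_time_mean / k)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        nid = f"N{counter}"
        counter += 1
        nodes[nid] = Node(nid, children=[a, b], time=t)
        nodes[a].parent = nid
        nodes[b].parent = nid
        active[i] = nid
        del active[j]
    return PhyloTree(nodes, active[0])


def true_node_times(tree: PhyloTree) -> NodeTimes:
    return NodeTimes(
        {nid: float(n.time) for nid, n in tree.nodes.items()},
        converged=True,
        log_likelihood=np.nan,
    )


def toy_genome(rng: np.random.Generator, excluded_sites: tuple[int, ...] = ()) -> AnnotatedGenome:
    """A ~2.9 kb circular toy genome echoing the mtDNA region mix.

    Four protein-coding genes (one on the light strand), one rRNA, one
    tRNA, one control region with two sub-regions, and a short unannotated
    spacer so that out-of-region sites exist.
    """
    plan = [
        Region("PC1", "protein_coding", 1, 600),
        Region("PC2", "protein_coding", 601, 1050),
        Region("PC3", "protein_coding", 1051, 1650),
        Region("PC4", "protein_coding", 1651, 1950, strand="light"),
        Region("RNR1", "rRNA", 1951, 2400),
        Region("TRN1", "tRNA", 2401, 2472),
        Region("HVS1", "control_subregion", 2473, 2672),
        Region("HVS2", "control_subregion", 2673, 2872),
    ]
    n = 2900  # leaves a 28-site unannotated spacer before wrapping to site 1
    seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])
    return AnnotatedGenome(seq, plan, excluded_sites=excluded_sites)


def simulate_covariates(
    genome: AnnotatedGenome, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-site numeric covariates: a conservation-like score and a domain flag."""
    n = len(genome)
    return pd.DataFrame(
        {
            "conservation": rng.normal(0.0, 1.0, size=n).round(4),
            "domain": rng.integers(0, 2, size=n).astype(float),
        },
        index=pd.RangeIndex(1, n + 1, name="site"),
    )


def _log_rate_components(
    genome: AnnotatedGenome,
    model: TrueModel,
    covariates: pd.DataFrame | None,
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Static log-rate part per site plus lookup vectors for dynamic factors."""
    gidx = genome.index
    n = gidx.n
    static = np.full(n, model.intercept, dtype=float)
    eff = {k: dict(v) for k, v in model.effects.items()}

    def add_static(values: np.ndarray, factor: str) -> None:
        table = eff.get(factor)
        if table:
            static_add = np.array([table.get(str(v), 0.0) for v in values])
            np.add(static, static_add, out=static)

    add_static(gidx.codon_pos, "codon_position")
    add_static(gidx.directionality, "directionality")
    region_names = np.array(
        [genome.regions[i].name if i >= 0 else "" for i in gidx.region_idx],
        dtype=object,
    )
    add_static(region_names, "gene")
    if covariates is not None:
        for col, coef in model.covariate_effects.items():
            name = col if col in covariates.columns else col.removeprefix("cov_")
            vals = covariates[name].reindex(pd.RangeIndex(1, n + 1)).fillna(0.0)
            static += coef * vals.to_numpy()

    lookups: dict[str, np.ndarray] = {}
    for factor, levels in [
        ("nucleotide", BASES),
        ("left_neighbor", BASES),
        ("right_neighbor", BASES),
        ("cpg", ["none", "first", "second"]),
    ]:
        table = eff.get(factor)
        if table:
            lookups[factor] = np.array([table.get(l, 0.0) for l in levels])
    for factor in ("codon", "amino_acid"):
        table = eff.get(factor)
        if table:
            from .genetic_code import AA_BY_CODON_INDEX, codon_from_index

            vec = np.zeros(65)
            for ci in range(64):
                key = codon_from_index(ci) if factor == "codon" else AA_BY_CODON_INDEX[ci]
                vec[ci] = table.get(key, 0.0)
            lookups[factor] = vec  # index 64 (= -1) is the non-coding slot

    # codon_position*<dynamic factor> interactions: (position 0..3, level) grids
    compound: dict[str, np.ndarray] = {}
    for key, table in eff.items():
        if "*" not in key:
            continue
        left_f, right_f = key.split("*", 1)
        if left_f != "codon_position":
            raise ValueError(
                f"compound effects must be codon_position*<factor>, got {key!r}"
            )
        levels = (
            ["none", "first", "second"] if right_f == "cpg" else list(BASES)
        )
        grid = np.zeros((4, len(levels)))
        for lev_key, coef in table.items():
            pos_s, lev = lev_key.split(":")
            grid[int(pos_s), levels.index(lev)] = coef
        compound[right_f] = grid
    return static, lookups, compound


def simulate_history(
    tree: PhyloTree,
    genome: AnnotatedGenome,
    config: SimulationConfig,
    covariates: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw substitution events along the tree under the true rate model.

    Fills every node's substitution list and sequence in place and returns
    the truth log: one row per event with branch, site, bases and the
    change class actually drawn.  Rates are evaluated in the parent-node
    state and counts drawn per site as Poisson(rate * duration).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    model = config.true_model
    n = len(genome)
    gidx = genome.index
    static, lookups, compound = _log_rate_components(genome, model, covariates)
    gamma = (
        rng.gamma(model.gamma_shape, 1.0 / model.gamma_shape, size=n)
        if model.gamma_shape is not None
        else np.ones(n)
    )
    root = tree.nodes[tree.root]
    root.sequence = genome.sequence
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    r = model.tv_ts_ratio
    p_ts = 1.0 / (1.0 + r)
    log: list[dict] = []
    codon_start0 = gidx.codon_start0
    has_codon = codon_start0 >= 0
    cs0 = np.clip(codon_start0, 0, None)
    c_code, g_code = BASES.index("C"), BASES.index("G")
    for parent, child in tree.branches():
        duration = parent.time - child.time
        seq = np.array(list(parent.sequence))
        codes = lut[np.frombuffer("".join(seq).encode(), dtype=np.uint8)].astype(int)
        lograte = static.copy()
        if "nucleotide" in lookups:
            lograte += lookups["nucleotide"][codes]
        if "left_neighbor" in lookups:
            lograte += lookups["left_neighbor"][np.roll(codes, 1)]
        if "right_neighbor" in lookups:
            lograte += lookups["right_neighbor"][np.roll(codes, -1)]
        if "cpg" in lookups or "cpg" in compound:
            right = np.roll(codes, -1)
            left = np.roll(codes, 1)
            cpg_code = np.where(
                (codes == c_code) & (right == g_code),
                1,
                np.where((codes == g_code) & (left == c_code), 2, 0),
            )
            if "cpg" in lookups:
                lograte += lookups["cpg"][cpg_code]
        for factor in ("codon", "amino_acid"):
            if factor in lookups:
                ci = np.where(
                    has_codon,
                    16 * codes[cs0] + 4 * codes[(cs0 + 1) % n] + codes[(cs0 + 2) % n],
                    64,
                )
                lograte += lookups[factor][ci]
        if compound:
            pos = gidx.codon_pos.astype(int)  # 0 outside codons
            dyn_codes = {
                "nucleotide": codes,
                "left_neighbor": np.roll(codes, 1),
                "right_neighbor": np.roll(codes, -1),
            }
            for dyn_factor, grid in compound.items():
                dyn = cpg_code if dyn_factor == "cpg" else dyn_codes[dyn_factor]
                lograte += grid[pos, dyn]
        lam = np.exp(lograte) * gamma * duration
        counts = rng.poisson(lam)
        child.substitutions = []
        for site0 in np.flatnonzero(counts):
            for _ in range(int(counts[site0])):
                from_base = seq[site0]
                if rng.random() < p_ts:
                    to_base = _TS_PARTNER[from_base]
                    change = "ts"
                else:
                    tv = [b for b in BASES if b != from_base and b != _TS_PARTNER[from_base]]
                    to_base = tv[int(rng.integers(0, 2))]
                    change = "tv"
                sub = Substitution(site=int(site0) + 1, from_base=from_base, to_base=to_base)
                child.substitutions.append(sub)
                log.append(
                    {
                        "branch_child": child.id,
                        "site": int(site0) + 1,
                        "from_base": from_base,
                        "to_base": to_base,
                        "change_class": change,
                    }
                )
                seq[site0] = to_base
        child.sequence = "".join(seq)
    return pd.DataFrame(
        log, columns=["branch_child", "site", "from_base", "to_base", "change_class"]
    )


@dataclass
class SimulatedDataset:
    """A complete synthetic study: inputs, ground truth and the tree itself."""

    tree: PhyloTree
    genome: AnnotatedGenome
    covariates: pd.DataFrame
    truth_log: pd.DataFrame
    true_times: NodeTimes
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "branches": outdir / "branches.tsv",
            "root_fasta": outdir / "root.fasta",
            "annotation": outdir / "annotation.tsv",
            "covariates": outdir / "covariates.tsv",
            "truth_log": outdir / "truth_log.tsv",
            "true_times": outdir / "true_times.tsv",
        }
        write_branch_table(self.tree, paths["branches"])
        write_reference(self.genome.sequence, paths["root_fasta"])
        write_annotation(self.genome.regions, paths["annotation"])
        write_covariates(self.covariates, paths["covariates"])
        self.truth_log.to_csv(paths["truth_log"], sep="\t", index=False)
        self.true_times.write(paths["true_times"])
        return paths


def simulate(config: SimulationConfig, genome: AnnotatedGenome | None = None) -> SimulatedDataset:
    """Generate a full synthetic dataset from one seed."""
    rng = np.random.default_rng(config.seed)
    if genome is None:
        genome = toy_genome(rng)
    covariates = simulate_covariates(genome, rng)
    tree = simulate_tree(config.n_tips, config.branch_time_mean, rng)
    truth = simulate_history(tree, genome, config, covariates, rng)
    return SimulatedDataset(
        tree=tree,
        genome=genome,
        covariates=covariates,
        truth_log=truth,
        true_times=true_node_times(tree),
        config=config,
    )
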