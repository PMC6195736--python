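"""State-exposure accounting: the regression table.

A *state* is the joint value at one site of every dynamic factor (codon,
neighbors, CpG, nucleotide); because the factors change along the tree as
substitutions accumulate, a site contributes one table row per distinct
state it passed through.  Each row accumulates the total uncalibrated tree
time spent in that state (the *exposure*) and the substitution counts
observed while in it, split into transitions/transversions and, at coding
sites, synonymous/non-synonymous changes.  The exposure enters log-link
count regressions as an offset, making expected counts proportional to
time at risk.

A branch's entire duration is attributed to the state at the branch's
start (the parent node); events are likewise credited to the state in
effect immediately before them.  Rows carry the number of *possible*
substitutions of each kind at their codon/position, which supplies the
extra offset used when synonymous and non-synonymous counts are modeled
separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .branch_time import NodeTimes
from .genetic_code import (
    AA_BY_CODON_INDEX,
    BASES,
    POSSIBLE_COUNTS,
    codon_from_index,
)
from .genome import AnnotatedGenome
from .phylo import PhyloTree, SubstitutionEvent, extract_events

#: sentinel returned by :func:`response_offset` for rows that cannot
#: contribute to a response mode (zero possible substitutions of that kind,
#: or zero exposure); such rows are dropped from the corresponding fit.
EXCLUDED = object()

RESPONSE_COLUMNS = {
    "all": "n_total",
    "ts": "n_ts",
    "tv": "n_tv",
    "syn": "n_syn",
    "nonsyn": "n_nonsyn",
}

_KEY = ["site", "codon_idx", "nt", "left", "right"]
_COUNTS = ["n_total", "n_ts", "n_tv", "n_syn", "n_nonsyn"]

# POSS[codon_idx, position-1] -> (syn_ts, syn_tv, nonsyn_ts, nonsyn_tv)
_POSS = np.array(
    [
        [
            [p.syn_ts, p.syn_tv, p.nonsyn_ts, p.nonsyn_tv]
            for p in POSSIBLE_COUNTS[ci]
        ]
        for ci in range(64)
    ],
    dtype=np.int64,
)


@dataclass
class StateExposureTable:
    """One row per (site, dynamic state), with exposure, counts and factors."""

    data: pd.DataFrame
    region_class: str | None
    total_tree_length: float
    covariate_columns: list[str] = field(default_factory=list)
    r: float | None = None

    def __len__(self) -> int:
        return len(self.data)

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def _seq_codes(sequence: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    return lut[np.frombuffer(sequence.encode(), dtype=np.uint8)]


def build_state_table(
    tree: PhyloTree,
    times: NodeTimes | Mapping[str, float],
    genome: AnnotatedGenome,
    clusters: Mapping[str, str] | None = None,
    covariates: pd.DataFrame | None = None,
    region_class: str | None = None,
    events: Sequence[SubstitutionEvent] | None = None,
) -> StateExposureTable:
    """Accumulate per-state exposure times and substitution counts.

    For every branch, the branch duration is added to the row keyed by each
    selected site's state at the parent node; every extracted event
    increments the counts of the row keyed by its own pre-substitution
    state.  ``region_class`` restricts the table to sites of that class
    (``None`` keeps every non-excluded site).  ``covariates`` is a numeric
    per-site frame indexed by site, joined onto the rows.
    """
    tmap = times.times if isinstance(times, NodeTimes) else dict(times)
    sites = genome.sites_of_class(region_class)
    if len(sites) == 0:
        raise ValueError(f"no sites of class {region_class!r}")
    sel0 = sites - 1
    n = len(genome)
    gidx = genome.index
    codon_start0 = gidx.codon_start0[sel0]
    has_codon = codon_start0 >= 0
    cs0 = np.clip(codon_start0, 0, None)

    blocks: list[dict[str, np.ndarray]] = []
    durations: list[float] = []
    total_length = 0.0
    for parent, child in tree.branches():
        duration = tmap[parent.id] - tmap[child.id]
        if duration < -1e-9:
            raise ValueError(
                f"negative branch duration on {parent.id}->{child.id}"
            )
        duration = max(duration, 0.0)
        total_length += duration
        if duration == 0.0:
            continue
        if parent.sequence is None:
            raise ValueError("sequences not propagated on the tree")
        s = _seq_codes(parent.sequence)
        codon_idx = np.where(
            has_codon,
            16 * s[cs0].astype(np.int64)
            + 4 * s[(cs0 + 1) % n]
            + s[(cs0 + 2) % n],
            -1,
        )
        blocks.append(
            {
                "site": sites,
                "codon_idx": codon_idx,
                "nt": s[sel0].astype(np.int64),
                "left": s[(sel0 - 1) % n].astype(np.int64),
                "right": s[(sel0 + 1) % n].astype(np.int64),
            }
        )
        durations.append(duration)

    frames = []
    if blocks:
        big = pd.DataFrame(
            {k: np.concatenate([b[k] for b in blocks]) for k in _KEY}
        )
        big["exposure"] = np.repeat(np.array(durations), len(sites))
        for col in _COUNTS:
            big[col] = 0
        frames.append(big)

    if events is None:
        events = extract_events(tree, genome, clusters)
    site_set = set(int(x) for x in sites)
    ev_rows = []
    base_idx = {b: i for i, b in enumerate(BASES)}
    for ev in events:
        if ev.site not in site_set:
            continue
        # counts are credited to the state at the branch start (the parent
        # node), mirroring the exposure attribution: when several events hit
        # one site on one branch, all of them belong to the state whose
        # rate was at risk for the branch's whole duration
        parent_id = tree.nodes[ev.branch_child].parent
        pseq = tree.nodes[parent_id].sequence
        i = ev.site - 1
        start0 = int(codon_start0[np.searchsorted(sites, ev.site)])
        if start0 >= 0:
            ci = (
                16 * base_idx[pseq[start0 % n]]
                + 4 * base_idx[pseq[(start0 + 1) % n]]
                + base_idx[pseq[(start0 + 2) % n]]
            )
        else:
            ci = -1
        ev_rows.append(
            {
                "site": ev.site,
                "codon_idx": ci,
                "nt": base_idx[pseq[i]],
                "left": base_idx[pseq[i - 1]],
                "right": base_idx[pseq[(i + 1) % n]],
                "exposure": 0.0,
                "n_total": 1,
                "n_ts": int(ev.change_class == "ts"),
                "n_tv": int(ev.change_class == "tv"),
                "n_syn": int(ev.synonymy == "syn"),
                "n_nonsyn": int(ev.synonymy == "nonsyn"),
            }
        )
    if ev_rows:
        frames.append(pd.DataFrame(ev_rows))
    if not frames:
        raise ValueError("tree has zero total length and no events")

    agg = (
        pd.concat(frames, ignore_index=True)
        .groupby(_KEY, sort=True, as_index=False)
        .sum()
    )

    table = _decorate(agg, genome, clusters)
    covariate_columns: list[str] = []
    if covariates is not None:
        cov = covariates.copy()
        cov.columns = [
            c if str(c).startswith("cov_") else f"cov_{c}" for c in cov.columns
        ]
        covariate_columns = list(cov.columns)
        table = table.merge(
            cov, how="left", left_on="site", right_index=True, validate="m:1"
        )
        for col in covariate_columns:
            table[col] = table[col].fillna(0.0)
    return StateExposureTable(
        data=table,
        region_class=region_class,
        total_tree_length=total_length,
        covariate_columns=covariate_columns,
    )


def _decorate(
    agg: pd.DataFrame,
    genome: AnnotatedGenome,
    clusters: Mapping[str, str] | None,
) -> pd.DataFrame:
    """Attach static factors, decoded sequence factors and possible counts."""
    gidx = genome.index
    sel0 = agg["site"].to_numpy() - 1
    ridx = gidx.region_idx[sel0]
    gene = np.array(
        [genome.regions[i].name if i >= 0 else "" for i in ridx], dtype=object
    )
    cmap = clusters or {}
    cluster = np.array([cmap.get(g, g) if g else "" for g in gene], dtype=object)
    rclass = np.array(
        [genome.regions[i].region_class if i >= 0 else "" for i in ridx],
        dtype=object,
    )
    codon_idx = agg["codon_idx"].to_numpy()
    codon_pos = gidx.codon_pos[sel0].astype(np.int64)
    codon_pos = np.where(codon_idx >= 0, codon_pos, 0)
    nt, left, right = (
        agg["nt"].to_numpy(),
        agg["left"].to_numpy(),
        agg["right"].to_numpy(),
    )
    bases = np.array(list(BASES))
    c_code, g_code = BASES.index("C"), BASES.index("G")
    cpg = np.where(
        (nt == c_code) & (right == g_code),
        "first",
        np.where((nt == g_code) & (left == c_code), "second", "none"),
    )
    codon_strings = np.array([codon_from_index(i) for i in range(64)] + [""])
    aa_strings = np.array(AA_BY_CODON_INDEX + [""])
    out = agg.copy()
    out["gene"] = gene
    out["cluster"] = cluster
    out["region_class"] = rclass
    out["nucleotide"] = bases[nt]
    out["left_neighbor"] = bases[left]
    out["right_neighbor"] = bases[right]
    out["cpg"] = cpg
    out["codon"] = codon_strings[codon_idx]
    out["amino_acid"] = aa_strings[codon_idx]
    out["codon_position"] = codon_pos
    out["directionality"] = gidx.directionality[sel0].astype(np.int64)
    poss = np.zeros((len(out), 4), dtype=np.int64)
    coding = codon_idx >= 0
    poss[coding] = _POSS[codon_idx[coding], codon_pos[coding] - 1]
    for j, col in enumerate(
        ["poss_syn_ts", "poss_syn_tv", "poss_nonsyn_ts", "poss_nonsyn_tv"]
    ):
        out[col] = poss[:, j]
    return out


def empirical_tv_ts_ratio(events: Iterable[SubstitutionEvent]) -> float:
    """Transversion/transition count ratio of an event list."""
    ts = tv = 0
    for ev in events:
        if ev.change_class == "ts":
            ts += 1
        else:
            tv += 1
    if ts == 0:
        raise ValueError("no transitions among events; ratio undefined")
    return tv / ts


def response_offset(row: Mapping[str, float], mode: str, r: float = 0.0):
    """Log-offset of one row for a response mode, or :data:`EXCLUDED`.

    For ``all``/``ts``/``tv`` the offset is ``log(exposure)``.  For ``syn``
    (``nonsyn``) it is ``log(exposure) + log(#ts_possible + r * #tv_possible)``
    where the possible counts are of the synonymous (non-synonymous) kind
    and ``r`` is the empirical transversion/transition ratio.  Rows with no
    possible substitution of the requested kind — e.g. position 1 of codon
    GTT for ``syn`` — cannot produce such events and are excluded.
    """
    if mode not in RESPONSE_COLUMNS:
        raise ValueError(f"unknown response mode {mode!r}")
    exposure = float(row["exposure"])
    if exposure < 0:
        raise ValueError("negative exposure")
    if exposure == 0.0:
        return EXCLUDED
    if mode in ("all", "ts", "tv"):
        return float(np.log(exposure))
    kind = "syn" if mode == "syn" else "nonsyn"
    weight = float(row[f"poss_{kind}_ts"]) + r * float(row[f"poss_{kind}_tv"])
    if weight <= 0:
        return EXCLUDED
    return float(np.log(exposure) + np.log(weight))


def response_offsets(
    table: StateExposureTable | pd.DataFrame, mode: str, r: float = 0.0
) -> tuple[str, np.ndarray, np.ndarray]:
    """Vectorized offsets: (response column, offset array, inclusion mask)."""
    df = table.data if isinstance(table, StateExposureTable) else table
    if mode not in RESPONSE_COLUMNS:
        raise ValueError(f"unknown response mode {mode!r}")
    exposure = df["exposure"].to_numpy(dtype=float)
    if np.any(exposure < 0):
        raise ValueError("negative exposure")
    mask = exposure > 0
    if mode in ("all", "ts", "tv"):
        weight = np.ones_like(exposure)
    else:
        kind = "syn" if mode == "syn" else "nonsyn"
        weight = (
            df[f"poss_{kind}_ts"].to_numpy(dtype=float)
            + r * df[f"poss_{kind}_tv"].to_numpy(dtype=float)
        )
        mask &= weight > 0
    offset = np.full(len(df), np.nan)
    offset[mask] = np.log(exposure[mask]) + np.log(weight[mask])
    return RESPONSE_COLUMNS[mode], offset, mask
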