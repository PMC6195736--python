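"""Annotated circular genome and per-site/per-context state derivation.

A genome is a circular sequence over ACGT with typed regions (protein
coding, rRNA, tRNA, control region and control sub-regions), a strand flag
per region and a reading-frame offset for coding regions.  The central
operation is :func:`site_state`: given a site and the full sequence carried
by a tree node, derive the joint value of every factor that can influence
the substitution rate at that site — gene, cluster, codon, amino acid,
nucleotide, codon position, flanking neighbors, CpG status and replication
directionality.

All coordinates are 1-based inclusive; neighbors wrap around the origin.
Sequence-derived factors (codon, neighbors, CpG) are evaluated on the
sequence orientation as written, for light-strand genes too; the strand
enters the models only through the directionality indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import (
    AA_BY_CODON_INDEX,
    BASE_INDEX,
    BASES,
    codon_from_index,
)

REGION_CLASSES = ("protein_coding", "rRNA", "tRNA", "control", "control_subregion")
STRANDS = ("heavy", "light")

CPG_NONE, CPG_FIRST, CPG_SECOND = "none", "first", "second"


@dataclass(frozen=True)
class Region:
    """One annotated region; ``start``/``end`` are 1-based inclusive."""

    name: str
    region_class: str
    start: int
    end: int
    strand: str = "heavy"
    frame: int = 0

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad region coordinates {self.start}..{self.end}")
        if self.region_class != "protein_coding" and self.frame != 0:
            raise ValueError("frame offset only applies to protein-coding regions")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class State:
    """The joint factor value of one site on one branch of the tree.

    Codon fields are ``None`` outside protein-coding regions.  ``cpg`` marks
    whether the site is the C (``"first"``) or the G (``"second"``) of a CpG
    dinucleotide in written orientation.
    """

    site: int
    region_class: str | None
    gene: str | None
    cluster: str | None
    nucleotide: str
    left_neighbor: str
    right_neighbor: str
    cpg: str
    directionality: int
    codon: str | None = None
    amino_acid: str | None = None
    codon_position: int | None = None
    site_covariates: Mapping[str, float] | None = None


class _GenomeIndex:
    """Vectorized per-site lookups, 0-based internally."""

    def __init__(self, genome: "AnnotatedGenome") -> None:
        n = len(genome.sequence)
        self.n = n
        self.seq_codes = np.frombuffer(
            genome.sequence.encode(), dtype=np.uint8
        ).copy()
        lut = np.full(256, 255, dtype=np.uint8)
        for b, i in BASE_INDEX.items():
            lut[ord(b)] = i
        self.seq_codes = lut[self.seq_codes]
        self.region_idx = np.full(n, -1, dtype=np.int32)
        self.codon_pos = np.zeros(n, dtype=np.int8)  # 1..3, 0 = not in a codon
        self.codon_start0 = np.full(n, -1, dtype=np.int64)
        self.directionality = np.zeros(n, dtype=np.int8)
        for ridx, region in enumerate(genome.regions):
            span = slice(region.start - 1, region.end)
            unset = self.region_idx[span] == -1
            idx0 = np.arange(region.start - 1, region.end)[unset]
            self.region_idx[idx0] = ridx
            if region.strand == "light":
                self.directionality[idx0] = 1
            if region.region_class == "protein_coding":
                coding0 = region.start - 1 + region.frame
                in_frame = idx0 >= coding0
                pos = (idx0[in_frame] - coding0) % 3
                self.codon_pos[idx0[in_frame]] = pos + 1
                self.codon_start0[idx0[in_frame]] = idx0[in_frame] - pos


class AnnotatedGenome:
    """Circular reference sequence plus typed regions and excluded sites."""

    def __init__(
        self,
        sequence: str,
        regions: Iterable[Region],
        excluded_sites: Iterable[int] = (),
    ) -> None:
        sequence = sequence.upper()
        if not sequence or any(b not in BASE_INDEX for b in set(sequence)):
            raise ValueError("sequence must be a non-empty string over ACGT")
        self.sequence = sequence
        self.regions = list(regions)
        self.excluded_sites = frozenset(int(s) for s in excluded_sites)
        n = len(sequence)
        for region in self.regions:
            if region.end > n:
                raise ValueError(f"region {region.name} exceeds sequence length {n}")
            if region.region_class == "protein_coding":
                if (len(region) - region.frame) % 3 != 0:
                    raise ValueError(
                        f"coding region {region.name}: length after frame offset "
                        "not divisible by 3"
                    )
        self._index: _GenomeIndex | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def index(self) -> _GenomeIndex:
        if self._index is None:
            self._index = _GenomeIndex(self)
        return self._index

    def region_at(self, site: int) -> Region | None:
        ridx = self.index.region_idx[site - 1]
        return None if ridx < 0 else self.regions[ridx]

    def sites_of_class(self, region_class: str | None) -> np.ndarray:
        """1-based non-excluded sites whose primary region has this class.

        ``region_class="control"`` also matches control sub-regions; ``None``
        returns every non-excluded site.
        """
        idx = self.index
        if region_class is None:
            mask = np.ones(idx.n, dtype=bool)
        else:
            classes = {region_class}
            if region_class == "control":
                classes.add("control_subregion")
            keep = np.array(
                [r.region_class in classes for r in self.regions], dtype=bool
            )
            mask = (idx.region_idx >= 0) & keep[np.clip(idx.region_idx, 0, None)]
        sites = np.flatnonzero(mask) + 1
        if self.excluded_sites:
            sites = sites[~np.isin(sites, sorted(self.excluded_sites))]
        return sites


def site_state(
    site: int,
    node_sequence: str,
    genome: AnnotatedGenome,
    clusters: Mapping[str, str] | None = None,
    covariates: Mapping[int, Mapping[str, float]] | None = None,
) -> State:
    """Derive the full factor state of ``site`` given a node's sequence.

    The sequence supplies the dynamic context (nucleotide, codon, neighbors,
    CpG); the genome annotation supplies the static factors.  Sites outside
    every region get ``region_class=None`` and remain usable.
    """
    n = len(genome.sequence)
    if len(node_sequence) != n:
        raise ValueError("node sequence length differs from reference")
    if site < 1 or site > n:
        raise ValueError(f"site {site} outside 1..{n}")
    if site in genome.excluded_sites:
        raise ValueError(f"site {site} is excluded from analysis")
    i = site - 1
    nt = node_sequence[i]
    left = node_sequence[i - 1]  # wraps for i == 0
    right = node_sequence[(i + 1) % n]
    if nt == "C" and right == "G":
        cpg = CPG_FIRST
    elif nt == "G" and left == "C":
        cpg = CPG_SECOND
    else:
        cpg = CPG_NONE
    region = genome.region_at(site)
    idx = genome.index
    codon = amino = None
    codon_position: int | None = None
    if region is not None and region.region_class == "protein_coding":
        pos = int(idx.codon_pos[i])
        if pos:
            start0 = int(idx.codon_start0[i])
            codon = "".join(
                node_sequence[(start0 + k) % n] for k in range(3)
            )
            codon_position = pos
            amino = AA_BY_CODON_INDEX[
                16 * BASE_INDEX[codon[0]] + 4 * BASE_INDEX[codon[1]] + BASE_INDEX[codon[2]]
            ]
    gene = region.name if region is not None else None
    cluster = None
    if gene is not None:
        cluster = (clusters or {}).get(gene, gene)
    return State(
        site=site,
        region_class=region.region_class if region is not None else None,
        gene=gene,
        cluster=cluster,
        nucleotide=nt,
        left_neighbor=left,
        right_neighbor=right,
        cpg=cpg,
        directionality=int(idx.directionality[i]),
        codon=codon,
        amino_acid=amino,
        codon_position=codon_position,
        site_covariates=dict(covariates[site]) if covariates and site in covariates else None,
    )


# ---------------------------------------------------------------------------
# External formats


def read_annotation(path: str | Path) -> list[Region]:
    """Read a region annotation TSV (name, class, start, end, strand, frame)."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str})
    required = {"name", "class", "start", "end", "strand", "frame"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    return [
        Region(
            name=row["name"],
            region_class=row["class"],
            start=int(row["start"]),
            end=int(row["end"]),
            strand=row["strand"],
            frame=int(row["frame"]),
        )
        for _, row in df.iterrows()
    ]


def write_annotation(regions: Iterable[Region], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "name": r.name,
                "class": r.region_class,
                "start": r.start,
                "end": r.end,
                "strand": r.strand,
                "frame": r.frame,
            }
            for r in regions
        ]
    ).to_csv(path, sep="\t", index=False)


def read_reference(path: str | Path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected a single FASTA record, found {len(records)}")
    return str(records[0].seq).upper()


def write_reference(sequence: str, path: str | Path, name: str = "root") -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read a per-site numeric covariate TSV; first column must be ``site``."""
    df = pd.read_csv(path, sep="\t")
    if "site" not in df.columns:
        raise ValueError("covariate file must have a 'site' column")
    df = df.set_index("site")
    return df.astype(float)


def write_covariates(df: pd.DataFrame, path: str | Path) -> None:
    df.reset_index().to_csv(path, sep="\t", index=False)
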