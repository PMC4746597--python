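"""Core data containers and readers/writers for the formats the pipeline touches.

All coordinates are 0-based half-open internally.  VCF and GFF3 use their
native 1-based conventions at the file boundary only, so there is a single
conversion point in each reader/writer.

Dosage encoding: 0 = homozygous reference, 1 = heterozygous (any phase),
2 = homozygous alternate, :data:`MISSING` (-1) = no call.  Missing is a
distinct sentinel, never 0, because 0 is a valid homozygous-reference call.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

#: Sentinel for a missing dosage call.
MISSING: int = -1

VARIANT_COLUMNS = ("chrom", "pos", "id", "ref", "alt")

_NUCS = frozenset("ACGT")


class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


class EmptyInputError(ValueError):
    """An input yielded no usable records."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for variants x samples.

    Attributes
    ----------
    variants : pandas.DataFrame
        Columns ``chrom`` (str), ``pos`` (int, 0-based), ``id``, ``ref``,
        ``alt``; sorted by (chrom, pos) with no duplicate (chrom, pos).
    samples : list of str
        Sample labels, one per dosage column.
    dosage : numpy.ndarray of int8, shape (n_variants, n_samples)
        Values in {0, 1, 2} or :data:`MISSING`.
    """

    variants: pd.DataFrame
    samples: list[str]
    dosage: np.ndarray

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, subset: Sequence[str]) -> np.ndarray:
        """Column indices for *subset*, raising on unknown labels."""
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in subset if s not in lookup]
        if missing:
            raise KeyError(f"unknown samples: {missing[:5]}")
        return np.asarray([lookup[s] for s in subset], dtype=np.intp)

    def subset_samples(self, subset: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(subset)
        return GenotypeMatrix(
            variants=self.variants.reset_index(drop=True),
            samples=list(subset),
            dosage=self.dosage[:, idx],
        )

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Row-subset by boolean mask or integer index (order-preserving)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            variants=self.variants.iloc[index].reset_index(drop=True),
            samples=list(self.samples),
            dosage=self.dosage[index],
        )

    def validate(self) -> None:
        v = self.variants
        if list(v.columns[:5]) != list(VARIANT_COLUMNS):
            raise ValueError(f"variant columns must start with {VARIANT_COLUMNS}")
        if self.dosage.shape != (len(v), len(self.samples)):
            raise ValueError("dosage shape does not match variants x samples")
        ok = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("dosage values outside {0,1,2,missing}")
        key = list(zip(v["chrom"], v["pos"]))
        if len(set(key)) != len(key):
            raise ValueError("duplicate (chrom, pos)")
        # sorted by (chrom, pos): chromosome blocks contiguous, pos ascending
        by_chrom: dict[str, int] = {}
        last_chrom, last_pos = None, -1
        for chrom, pos in key:
            if chrom != last_chrom:
                if chrom in by_chrom:
                    raise ValueError("variants not grouped by chromosome")
                by_chrom[chrom] = 1
                last_chrom, last_pos = chrom, -1
            if pos < last_pos:
                raise ValueError("positions not sorted within chromosome")
            last_pos = pos


@dataclasses.dataclass
class GenomeLayout:
    """Chromosome names/lengths and optional pericentromeric intervals."""

    chromosomes: list[tuple[str, int]]
    pericentromeric: list[tuple[str, int, int]] = dataclasses.field(default_factory=list)

    @property
    def total_bp(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def validate(self) -> None:
        lengths = self.lengths()
        if any(L <= 0 for L in lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        seen: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.pericentromeric:
            if chrom not in lengths:
                raise ValueError(f"pericentromeric interval on unknown chromosome {chrom}")
            if not (0 <= start < end <= lengths[chrom]):
                raise ValueError("pericentromeric interval outside chromosome bounds")
            seen.setdefault(chrom, []).append((start, end))
        for chrom, ivals in seen.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping pericentromeric intervals on {chrom}")


@dataclasses.dataclass
class GeneSet:
    """Gene spans plus optional sub-features (CDS/intron/UTR5/UTR3).

    ``genes``: DataFrame with id, chrom, start, end, strand (0-based half-open).
    ``features``: DataFrame with gene_id, kind, start, end; kind is one of
    CDS, intron, UTR5, UTR3.
    """

    genes: pd.DataFrame
    features: pd.DataFrame = dataclasses.field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "kind", "start", "end"])
    )

    def __len__(self) -> int:
        return len(self.genes)

    def validate(self) -> None:
        g = self.genes
        if len(g) and not (g["start"] < g["end"]).all():
            raise ValueError("gene start must be < end")
        if g["id"].duplicated().any():
            raise ValueError("duplicate gene ids")
        if len(self.features):
            span = g.set_index("id")
            for gid, grp in self.features.groupby("gene_id"):
                if gid not in span.index:
                    raise ValueError(f"feature for unknown gene {gid}")
                if (grp["start"] < span.at[gid, "start"]).any() or (
                    grp["end"] > span.at[gid, "end"]
                ).any():
                    raise ValueError(f"sub-feature outside gene span for {gid}")


def make_metadata(
    samples: Sequence[str],
    population: Sequence[str],
    evolution_type: Sequence[str] | None = None,
    eco_region: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build a sample-metadata table (population in {wild, cultivated})."""
    n = len(samples)
    if evolution_type is None:
        evolution_type = ["wild" if p == "wild" else "unknown" for p in population]
    if eco_region is None:
        eco_region = ["unknown"] * n
    meta = pd.DataFrame(
        {
            "sample": list(samples),
            "population": list(population),
            "evolution_type": list(evolution_type),
            "eco_region": list(eco_region),
        }
    )
    validate_metadata(meta)
    return meta


def validate_metadata(meta: pd.DataFrame, matrix: GenotypeMatrix | None = None) -> None:
    required = {"sample", "population", "evolution_type", "eco_region"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata missing columns {required - set(meta.columns)}")
    if not meta["population"].isin(["wild", "cultivated"]).all():
        raise ValueError("population must be wild or cultivated")
    if not meta["evolution_type"].isin(["wild", "landrace", "improved", "unknown"]).all():
        raise ValueError("bad evolution_type")
    if not meta["eco_region"].isin(["NR", "HR", "SR", "unknown"]).all():
        raise ValueError("bad eco_region")
    wild = meta["population"] == "wild"
    if not (meta.loc[wild, "evolution_type"] == "wild").all():
        raise ValueError("population=wild implies evolution_type=wild")
    if meta["sample"].duplicated().any():
        raise ValueError("duplicate sample rows")
    if matrix is not None:
        if set(matrix.samples) - set(meta["sample"]):
            raise ValueError("samples in genotype matrix missing from metadata")


def population_samples(meta: pd.DataFrame, population: str) -> list[str]:
    return meta.loc[meta["population"] == population, "sample"].tolist()


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a VCF (GT field) into a :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP records are dropped (count logged); duplicate
    (chrom, pos) records after the first are dropped likewise.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows: list[tuple] = []
    dosages: list[np.ndarray] = []
    seen: set[tuple[str, int]] = set()
    dropped = 0
    for v in vcf:
        alts = v.ALT
        if (
            len(alts) != 1
            or len(v.REF) != 1
            or len(alts[0]) != 1
            or v.REF not in _NUCS
            or alts[0] not in _NUCS
        ):
            dropped += 1
            continue
        key = (v.CHROM, v.POS - 1)
        if key in seen:
            dropped += 1
            continue
        seen.add(key)
        gt = v.gt_types  # 0=homref, 1=het, 2=unknown, 3=homalt
        d = np.full(len(samples), MISSING, dtype=np.int8)
        d[gt == 0] = 0
        d[gt == 1] = 1
        d[gt == 3] = 2
        rows.append((v.CHROM, v.POS - 1, v.ID or f"{v.CHROM}_{v.POS}", v.REF, alts[0]))
        dosages.append(d)
    if dropped:
        log.info("read_genotypes: dropped %d non-biallelic-SNP/duplicate records", dropped)
    if not rows:
        raise EmptyInputError(f"no biallelic SNPs retained from {path}")
    variants = pd.DataFrame(rows, columns=list(VARIANT_COLUMNS))
    dosage = np.vstack(dosages)
    order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
    m = GenotypeMatrix(
        variants=variants.iloc[order].reset_index(drop=True),
        samples=samples,
        dosage=dosage[order],
    )
    m.validate()
    return m


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotypes(m: GenotypeMatrix, path: str | Path, layout: GenomeLayout | None = None) -> None:
    """Write a minimal VCF 4.2 with GT-only FORMAT (round-trips with read)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if layout is not None:
            for chrom, length in layout.chromosomes:
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(m.samples) + "\n")
        v = m.variants
        for i in range(m.n_variants):
            gts = "\t".join(_GT_STR[int(x)] for x in m.dosage[i])
            fh.write(
                f"{v.at[i, 'chrom']}\t{v.at[i, 'pos'] + 1}\t{v.at[i, 'id']}\t"
                f"{v.at[i, 'ref']}\t{v.at[i, 'alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_KIND_MAP = {
    "CDS": "CDS",
    "intron": "intron",
    "five_prime_UTR": "UTR5",
    "three_prime_UTR": "UTR3",
}


def _gff_attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            continue
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_genes(path: str | Path) -> GeneSet:
    """Parse GFF3 gene features (with optional CDS/intron/UTR children)."""
    genes: list[tuple] = []
    feats: list[tuple] = []
    id_of: dict[str, str] = {}  # feature ID -> owning gene id
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = cols
            try:
                start0, end1 = int(start) - 1, int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            a = _gff_attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID", f"gene:{chrom}:{start}")
                genes.append((gid, chrom, start0, end1, strand))
                id_of[gid] = gid
            elif ftype in _KIND_MAP:
                parent = a.get("Parent")
                if parent is None:
                    continue
                # parent may be an mRNA; resolve through one level if known
                gid = id_of.get(parent, parent)
                feats.append((gid, _KIND_MAP[ftype], start0, end1))
            elif ftype == "mRNA":
                parent = a.get("Parent")
                if parent is not None and "ID" in a:
                    id_of[a["ID"]] = id_of.get(parent, parent)
    if not genes:
        warnings.warn(f"no gene features in {path}", stacklevel=2)
    gdf = pd.DataFrame(genes, columns=["id", "chrom", "start", "end", "strand"])
    fdf = pd.DataFrame(feats, columns=["gene_id", "kind", "start", "end"])
    known = set(gdf["id"])
    fdf = fdf[fdf["gene_id"].isin(known)].reset_index(drop=True)
    gs = GeneSet(genes=gdf, features=fdf)
    gs.validate()
    return gs


def write_genes(gs: GeneSet, path: str | Path) -> None:
    """Write a GeneSet as GFF3 (inverse of :func:`read_genes`)."""
    kind_inv = {v: k for k, v in _KIND_MAP.items()}
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        groups = dict(tuple(gs.features.groupby("gene_id"))) if len(gs.features) else {}
        for _, g in gs.genes.iterrows():
            fh.write(
                f"{g['chrom']}\tdomscan\tgene\t{g['start'] + 1}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\tID={g['id']}\n"
            )
            if g["id"] in groups:
                for _, f in groups[g["id"]].iterrows():
                    fh.write(
                        f"{g['chrom']}\tdomscan\t{kind_inv[f['kind']]}\t"
                        f"{f['start'] + 1}\t{f['end']}\t.\t{g['strand']}\t.\t"
                        f"ID={g['id']}.{f['kind']}.{f['start']};Parent={g['id']}\n"
                    )


# ---------------------------------------------------------------------------
# SNP context classification
# ---------------------------------------------------------------------------

#: Precedence when sub-features overlap (highest first).
CONTEXT_PRECEDENCE = ("CDS", "UTR5", "UTR3", "intron", "genic-other", "intergenic")


def classify_snp_context(m: GenotypeMatrix, genes: GeneSet) -> pd.Series:
    """Label every SNP as CDS/intron/UTR5/UTR3/genic-other/intergenic.

    Exactly one label per SNP; overlapping annotations resolved by
    :data:`CONTEXT_PRECEDENCE`.  SNPs on chromosomes absent from the
    annotation are intergenic (with a warning).
    """
    trees: dict[str, dict[str, IntervalTree]] = {}

    def tree(chrom: str, kind: str) -> IntervalTree:
        return trees.setdefault(chrom, {}).setdefault(kind, IntervalTree())

    for _, g in genes.genes.iterrows():
        tree(g["chrom"], "gene").addi(g["start"], g["end"], g["id"])
    if len(genes.features):
        chrom_of = dict(zip(genes.genes["id"], genes.genes["chrom"]))
        for _, f in genes.features.iterrows():
            tree(chrom_of[f["gene_id"]], f["kind"]).addi(f["start"], f["end"], f["gene_id"])

    known_chroms = set(trees)
    unknown = set(m.variants["chrom"]) - known_chroms
    if unknown and len(genes.genes):
        warnings.warn(f"chromosomes without annotation treated as intergenic: {sorted(unknown)}")

    labels = np.full(m.n_variants, "intergenic", dtype=object)
    chroms = m.variants["chrom"].to_numpy()
    pos = m.variants["pos"].to_numpy()
    for i in range(m.n_variants):
        t = trees.get(chroms[i])
        if t is None or not t.get("gene", IntervalTree()).overlap(pos[i], pos[i] + 1):
            continue
        for kind in ("CDS", "UTR5", "UTR3", "intron"):
            if kind in t and t[kind].overlap(pos[i], pos[i] + 1):
                labels[i] = kind
                break
        else:
            labels[i] = "genic-other"
    return pd.Series(labels, name="context")


# ---------------------------------------------------------------------------
# Tables, BED, Newick, FASTA
# ---------------------------------------------------------------------------


def write_windows(table: pd.DataFrame, path: str | Path) -> None:
    """Write a window-stats table as BED-compatible TSV (header kept)."""
    table.to_csv(path, sep="\t", index=False)


def read_windows(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_regions(regions: Iterable, path: str | Path) -> None:
    """Write sweep regions (anything with chrom/start/end) as BED."""
    with Path(path).open("w") as fh:
        for r in regions:
            chrom = getattr(r, "chrom", None) or r["chrom"]
            start = getattr(r, "start", None) if hasattr(r, "start") else r["start"]
            end = getattr(r, "end", None) if hasattr(r, "end") else r["end"]
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_tree(newick: str, path: str | Path) -> None:
    text = newick if newick.endswith("\n") else newick + "\n"
    Path(path).write_text(text)


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    validate_metadata(meta)
    return meta
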