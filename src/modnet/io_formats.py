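"""Readers and writers for the external formats the pipeline touches.

All coordinate-bearing readers convert to a single internal convention —
0-based, half-open intervals — at the I/O boundary (BED is already 0-based
half-open; VCF positions are 1-based and get shifted by one on the way in).
Downstream modules only ever see validated in-memory containers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

log = logging.getLogger(__name__)

#: sentinel for a missing genotype call in dosage matrices
MISSING_DOSAGE = -1


class FormatError(ValueError):
    """Structurally malformed input (bad header, wrong field count...)."""


class ValidationError(ValueError):
    """Well-formed input violating a semantic invariant (duplicate ids...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """One cohort's normalized genes x samples expression matrix.

    ``n_samples`` (the cohort size) is consumed downstream as a
    meta-analysis weight input. Expression units are taken as already
    normalized; the declared unit is carried as metadata only.
    """

    dataset_id: str
    species: str
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    unit: str = "normalized"
    constant_genes: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._index[gene_id]
        except AttributeError:
            self._index = {g: i for i, g in enumerate(self.gene_ids)}
            return self._index[gene_id]

    def validate(self) -> "ExpressionDataset":
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"dataset {self.dataset_id}: values shape {self.values.shape} "
                f"!= ({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise ValidationError(
                f"dataset {self.dataset_id}: duplicate gene ids {sorted(dupes)}"
            )
        if not np.all(np.isfinite(self.values)):
            bad = int(np.sum(~np.isfinite(self.values)))
            raise ValidationError(
                f"dataset {self.dataset_id}: {bad} non-finite expression entries"
            )
        # constant rows are recorded, not dropped: correlation-based steps
        # must exclude them but other consumers may still want the rows
        sd = self.values.std(axis=1)
        self.constant_genes = [g for g, s in zip(self.gene_ids, sd) if s == 0.0]
        if self.constant_genes:
            log.warning(
                "dataset %s: %d constant-expression genes flagged",
                self.dataset_id,
                len(self.constant_genes),
            )
        return self


@dataclass
class ModuleCatalog:
    """Named gene sets (ontology terms / co-expression modules) over a universe."""

    modules: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def genes(self, module_id: str) -> frozenset[str]:
        return self.modules[module_id][1]

    def __contains__(self, module_id: str) -> bool:
        return module_id in self.modules

    def __len__(self) -> int:
        return len(self.modules)

    @property
    def module_ids(self) -> list[str]:
        return list(self.modules)

    def filtered(self, min_size: int = 5) -> "ModuleCatalog":
        """Catalog restricted to modules with at least ``min_size`` genes."""
        kept = {m: v for m, v in self.modules.items() if len(v[1]) >= min_size}
        return ModuleCatalog(kept, self.universe)

    def validate(self) -> "ModuleCatalog":
        for mid, (_, genes) in self.modules.items():
            stray = genes - self.universe
            if stray:
                raise ValidationError(
                    f"module {mid}: {len(stray)} genes outside the universe "
                    f"(e.g. {sorted(stray)[:3]})"
                )
        return self


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene body coordinates, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand {self.strand!r}")


@dataclass
class GenotypeMatrix:
    """Biallelic dosages in {0,1,2}; missing calls encoded as MISSING_DOSAGE."""

    variant_ids: list[str]
    positions: list[tuple[str, int]]  # (chrom, 0-based bp)
    samples: list[str]
    dosages: np.ndarray  # variants x samples, int8

    def validate(self) -> "GenotypeMatrix":
        ok = np.isin(self.dosages, (0, 1, 2, MISSING_DOSAGE))
        if not ok.all():
            raise ValidationError("dosages outside {0,1,2,missing}")
        return self

    def maf(self) -> np.ndarray:
        """Per-variant minor-allele frequency over non-missing calls."""
        d = np.ma.masked_equal(self.dosages, MISSING_DOSAGE)
        af = d.mean(axis=1).filled(np.nan) / 2.0
        return np.minimum(af, 1.0 - af)

    def monomorphic(self) -> np.ndarray:
        d = np.ma.masked_equal(self.dosages, MISSING_DOSAGE)
        return (d.max(axis=1) == d.min(axis=1)).filled(True)


@dataclass
class MethylationBins:
    """Fixed-width methylation bins used as pseudo-genotypes.

    ``levels`` holds the per-sample methylation fraction in [0,1] for each
    bin; the ``context`` of each bin is CG / CH / C (the paper's DMB classes).
    """

    bin_ids: list[str]
    coords: list[tuple[str, int, int]]  # (chrom, start, end), 0-based half-open
    samples: list[str]
    levels: np.ndarray  # bins x samples, float
    contexts: list[str] = field(default_factory=list)
    bin_width: int = 100

    def validate(self) -> "MethylationBins":
        widths = {e - s for _, s, e in self.coords}
        if widths and widths != {self.bin_width}:
            raise ValidationError(f"bin widths {sorted(widths)} != {self.bin_width}")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c, s, e in self.coords:
            by_chrom.setdefault(c, []).append((s, e))
        for c, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValidationError(f"overlapping bins on {c} at {s2}")
        if np.nanmin(self.levels) < 0 or np.nanmax(self.levels) > 1:
            raise ValidationError("methylation levels outside [0,1]")
        return self


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    weight: float
    sign: int  # +1 / -1
    evidence: str = ""


@dataclass
class EdgeTable:
    """Directed weighted signed edges (TF->target priors, correlation edges)."""

    edges: list[Edge]

    def __len__(self) -> int:
        return len(self.edges)

    def validate(self, allow_self: bool = False) -> "EdgeTable":
        if not allow_self:
            loops = [e for e in self.edges if e.source == e.target]
            if loops:
                raise ValidationError(f"{len(loops)} self-edges (e.g. {loops[0].source})")
        # duplicate (source, target) pairs collapse deterministically: keep max |weight|,
        # ties resolved by the first occurrence
        best: dict[tuple[str, str], Edge] = {}
        for e in self.edges:
            k = (e.source, e.target)
            if k not in best or abs(e.weight) > abs(best[k].weight):
                best[k] = e
        self.edges = list(best.values())
        return self


@dataclass
class HomologyHitTable:
    """BLAST-style homology hits between two species' proteomes."""

    hits: pd.DataFrame  # query, subject, query_species, subject_species, e_value, pct_identity

    COLUMNS = ("query", "subject", "query_species", "subject_species", "e_value", "pct_identity")

    def validate(self) -> "HomologyHitTable":
        missing = set(self.COLUMNS) - set(self.hits.columns)
        if missing:
            raise FormatError(f"homology table missing columns {sorted(missing)}")
        if (self.hits["e_value"] < 0).any():
            raise ValidationError("negative E-values")
        pid = self.hits["pct_identity"]
        if ((pid < 0) | (pid > 100)).any():
            raise ValidationError("percent identity outside [0,100]")
        return self


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# expression matrices (TSV and MatrixMarket triple)
# ---------------------------------------------------------------------------


def read_expression(
    path: str | Path,
    dataset_id: str,
    species: str = "unknown",
    unit: str = "normalized",
) -> ExpressionDataset:
    """Read a genes x samples matrix.

    ``path`` is either a TSV (header row of sample ids, first column of gene
    ids) or a MatrixMarket ``.mtx`` file; in the latter case gene and sample
    ids are read from sibling ``<stem>.genes.txt`` / ``<stem>.samples.txt``.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = path.with_suffix("").with_suffix(".genes.txt").read_text().split()
        samples = path.with_suffix("").with_suffix(".samples.txt").read_text().split()
        ds = ExpressionDataset(dataset_id, species, genes, samples, np.asarray(mat, float), unit)
        return ds.validate()

    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype={0: str})
    except Exception as exc:  # noqa: BLE001 - rewrap as format error
        raise FormatError(f"{path}: cannot parse TSV header/body: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns in header")
    dupes = _duplicates(df.index.astype(str))
    if dupes:
        raise ValidationError(f"{path}: duplicate gene ids {sorted(dupes)}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().any() and not df[col].isna().any():
                i = int(np.argmax(bad.isna().to_numpy()))
                raise FormatError(
                    f"{path}: non-numeric cell at gene {df.index[i]!r}, sample {col!r}"
                ) from None
        raise
    ds = ExpressionDataset(
        dataset_id, species, [str(g) for g in df.index], [str(s) for s in df.columns], values, unit
    )
    return ds.validate()


def write_expression(ds: ExpressionDataset, path: str | Path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(ds.values))
        path.with_suffix("").with_suffix(".genes.txt").write_text("\n".join(ds.gene_ids) + "\n")
        path.with_suffix("").with_suffix(".samples.txt").write_text("\n".join(ds.sample_ids) + "\n")
        return
    df = pd.DataFrame(ds.values, index=ds.gene_ids, columns=ds.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# GMT gene-set catalogs
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> ModuleCatalog:
    """Standard GMT: name <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    path = Path(path)
    modules: dict[str, tuple[str, frozenset[str]]] = {}
    text = path.read_text()
    if not text.strip():
        log.warning("%s: empty GMT, returning empty catalog", path)
        return ModuleCatalog({}, frozenset(universe or ()))
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
        name, desc, *genes = fields
        modules[name] = (desc, frozenset(g for g in genes if g))
    if universe is None:
        uni = frozenset().union(*(g for _, g in modules.values()))
    else:
        uni = frozenset(universe)
    return ModuleCatalog(modules, uni).validate()


def write_gmt(catalog: ModuleCatalog, path: str | Path) -> None:
    lines = []
    for name, (desc, genes) in catalog.modules.items():
        lines.append("\t".join([name, desc or "na", *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# genotypes (VCF via pysam, or plain dosage TSV)
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a VCF (biallelic GT records) or a 0/1/2 dosage TSV.

    VCF positions are converted to 0-based; multi-allelic records are
    skipped with a logged count; ``./.`` becomes a missing call.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".VCF") or path.name.endswith(".vcf.gz"):
        return _read_vcf(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not {"chrom", "pos"}.issubset(df.columns):
        raise FormatError(f"{path}: dosage TSV needs 'chrom' and 'pos' columns")
    samples = [c for c in df.columns if c not in ("chrom", "pos")]
    dos = df[samples].to_numpy()
    dos = np.where(pd.isna(dos), MISSING_DOSAGE, dos).astype(np.int8)
    gm = GenotypeMatrix(
        variant_ids=[str(v) for v in df.index],
        positions=[(str(c), int(p)) for c, p in zip(df["chrom"], df["pos"])],
        samples=samples,
        dosages=dos,
    )
    return gm.validate()


def _read_vcf(path: Path) -> GenotypeMatrix:
    import pysam

    variant_ids, positions, rows = [], [], []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        if "GT" not in vf.header.formats:
            raise FormatError(f"{path}: VCF has no GT FORMAT field")
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            row = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT", (None, None))
                if gt is None or any(a is None for a in gt):
                    row[i] = MISSING_DOSAGE
                else:
                    row[i] = int(sum(1 for a in gt if a != 0))
            variant_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            positions.append((rec.chrom, rec.pos - 1))  # 1-based -> 0-based
            rows.append(row)
    if skipped:
        log.info("%s: skipped %d multi-allelic records", path, skipped)
    gm = GenotypeMatrix(variant_ids, positions, samples, np.array(rows, dtype=np.int8))
    gm.n_skipped_multiallelic = skipped  # type: ignore[attr-defined]
    return gm.validate()


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2 writer (GT only), converting back to 1-based positions."""
    chroms = sorted({c for c, _ in gm.positions})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples))
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING_DOSAGE: "./."}
    for vid, (chrom, pos), row in zip(gm.variant_ids, gm.positions, gm.dosages):
        gts = "\t".join(code[int(d)] for d in row)
        lines.append(f"{chrom}\t{pos + 1}\t{vid}\tA\tT\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_dosage_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(gm.dosages, index=gm.variant_ids, columns=gm.samples)
    df.insert(0, "chrom", [c for c, _ in gm.positions])
    df.insert(1, "pos", [p for _, p in gm.positions])
    df = df.replace(MISSING_DOSAGE, pd.NA)
    df.index.name = "variant_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# BED (gene annotations / methylation bin coordinates)
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GeneAnnotation]:
    """BED 4+ -> gene annotations. BED is already 0-based half-open."""
    anns = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 4:
            raise FormatError(f"{path}:{lineno}: BED needs >= 4 columns (chrom start end name)")
        strand = f[5] if len(f) >= 6 else "+"
        anns.append(GeneAnnotation(f[3], f[0], int(f[1]), int(f[2]), strand))
    return anns


def write_bed(anns: Sequence[GeneAnnotation], path: str | Path) -> None:
    lines = [f"{a.chrom}\t{a.start}\t{a.end}\t{a.gene_id}\t0\t{a.strand}" for a in anns]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_methylation(
    bed_path: str | Path, levels_path: str | Path, bin_width: int = 100
) -> MethylationBins:
    """Bin coordinates from BED (name column = bin id, score column = context),
    per-sample levels from a TSV keyed by bin id."""
    coords, bin_ids, contexts = [], [], []
    for lineno, line in enumerate(Path(bed_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) < 4:
            raise FormatError(f"{bed_path}:{lineno}: bin BED needs >= 4 columns")
        bin_ids.append(f[3])
        coords.append((f[0], int(f[1]), int(f[2])))
        contexts.append(f[4] if len(f) >= 5 else "C")
    df = pd.read_csv(levels_path, sep="\t", index_col=0)
    df = df.loc[bin_ids]
    mb = MethylationBins(
        bin_ids, coords, [str(s) for s in df.columns], df.to_numpy(float), contexts, bin_width
    )
    return mb.validate()


def write_methylation(mb: MethylationBins, bed_path: str | Path, levels_path: str | Path) -> None:
    ctx = mb.contexts or ["C"] * len(mb.bin_ids)
    lines = [
        f"{c}\t{s}\t{e}\t{b}\t{x}"
        for (c, s, e), b, x in zip(mb.coords, mb.bin_ids, ctx)
    ]
    Path(bed_path).write_text("\n".join(lines) + "\n")
    df = pd.DataFrame(mb.levels, index=mb.bin_ids, columns=mb.samples)
    df.index.name = "bin_id"
    df.to_csv(levels_path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# edge lists and homology hits
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ["source", "target", "weight", "sign", "evidence"]


def read_edges(path: str | Path, allow_self: bool = False) -> EdgeTable:
    df = pd.read_csv(path, sep="\t", header=0)
    missing = set(_EDGE_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: edge list missing columns {sorted(missing)}")
    if "evidence" not in df.columns:
        df["evidence"] = ""
    edges = [
        Edge(str(r.source), str(r.target), float(r.weight), int(r.sign), str(r.evidence))
        for r in df.itertuples()
    ]
    return EdgeTable(edges).validate(allow_self=allow_self)


def write_edges(table: EdgeTable, path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.source, e.target, e.weight, e.sign, e.evidence) for e in table.edges],
        columns=_EDGE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_hits(path: str | Path) -> HomologyHitTable:
    df = pd.read_csv(path, sep="\t", header=0)
    return HomologyHitTable(df).validate()


def write_hits(table: HomologyHitTable, path: str | Path) -> None:
    table.hits.to_csv(path, sep="\t", index=False, float_format="%.10g")
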