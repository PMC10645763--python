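"""Readers, writers and in-memory containers for every external table format.

All downstream stages consume only the types defined here.  Conventions:

* genomic coordinates are 1-based inclusive (VCF convention) everywhere;
* missing genotype dosages are ``numpy.nan`` (never 0);
* every output table is TSV with a single header line, floats at 6
  significant digits, and an optional JSON sidecar recording the
  configuration and seed that produced it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene-by-sample abundance matrix (RPKM-like continuous values)."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {name} id: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])


@dataclass(frozen=True)
class VariantInfo:
    """A biallelic SNP with its effect-allele orientation."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", self.effect_allele.upper())
        object.__setattr__(self, "other_allele", self.other_allele.upper())
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: alleles must differ")
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1 (1-based)")

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class GenotypeMatrix:
    """Sample-by-SNP dosage matrix in [0, 2]; missing calls are NaN."""

    sample_ids: list[str]
    variants: list[VariantInfo]
    dosages: np.ndarray  # shape (n_samples, n_snps)

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("dosage shape inconsistent with ids")
        dup = _first_duplicate([v.snp_id for v in self.variants])
        if dup is not None:
            raise ValueError(f"duplicate variant id: {dup!r}")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def snp_ids(self) -> list[str]:
        return [v.snp_id for v in self.variants]

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_ids.index(snp_id)]


@dataclass(frozen=True)
class EQTLRecord:
    """Per-allele effect of a SNP on one gene's expression."""

    snp: VariantInfo
    gene_id: str
    beta: float
    se: float
    p: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.snp.snp_id}: se must be > 0")


@dataclass(frozen=True)
class GWASSummaryRecord:
    """Per-allele effect of a SNP on an outcome trait."""

    snp: VariantInfo
    beta: float
    se: float
    p: float
    eaf: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.snp.snp_id}: se must be > 0")
        if self.eaf is not None and not 0 < self.eaf < 1:
            raise ValueError(f"{self.snp.snp_id}: eaf must be in (0,1)")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics); descriptions retained but unused."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        self.descriptions = {k: self.descriptions.get(k, "") for k in self.sets}

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """All tunable stage parameters, defaulting to the published settings."""

    # network
    soft_power: int = 14
    signed: bool = True
    min_module_size: int = 30
    merge_cor_threshold: float = 0.85
    scale_free_target_r2: float = 0.8
    expressed_fraction: float = 0.9
    cut_height_frac: float = 0.99
    gap_frac: float = 0.25
    outlier_sd: float = 2.5
    # preservation
    n_permutations: int = 100
    # PGS
    clump_r2: float = 0.2
    clump_window_kb: float = 250.0
    gene_window_kb: float = 0.0
    missing_policy: str = "mean"  # mean | drop | zero
    # scoring
    ssgsea_tau: float = 0.25
    ssgsea_normalize: bool = True
    score_nbin: int = 24
    score_nctrl: int = 100
    # pheWAS / multiplicity
    fdr_level: float = 0.05
    min_nonmissing: int = 50
    # MR
    wm_bootstrap: int = 1000
    # ARACNE
    mi_bins: int = 5
    mi_permutations: int = 100
    mi_alpha: float = 0.05
    dpi_eps: float = 0.0
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        for name in ("merge_cor_threshold", "scale_free_target_r2",
                     "expressed_fraction", "cut_height_frac", "gap_frac",
                     "fdr_level", "mi_alpha", "clump_r2"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.missing_policy not in ("mean", "drop", "zero"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")
        for name in ("n_permutations", "mi_permutations", "wm_bootstrap",
                     "mi_bins", "min_module_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, strict_nonnegative: bool = False) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene ids, header sample ids).

    ``strict_nonnegative`` rejects negative abundances (RPKM-like input).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    dup = _first_duplicate(list(df.index.astype(str)))
    if dup is not None:
        raise ValueError(f"duplicate gene id in {path}: {dup!r}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression cell in {path}: {exc}") from exc
    if strict_nonnegative and (values < 0).any():
        raise ValueError(f"negative abundance values in {path}")
    return ExpressionMatrix(list(df.index.astype(str)),
                            list(df.columns.astype(str)), values)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    frame = expr.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format="%.10g")


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has < 3 fields")
            name, desc, members = fields[0], fields[1], [m for m in fields[2:] if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection[name]]) + "\n")


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str],
    kind: str = "gwas",
    sep: str = "\t",
) -> list[GWASSummaryRecord] | list[EQTLRecord]:
    """Read a delimited eQTL or GWAS summary-statistics table.

    ``column_map`` maps the canonical field names (snp, chrom, pos,
    effect_allele, other_allele, beta, se, p and, depending on ``kind``,
    gene / eaf / n) to the column names actually present in the file.
    Rows with missing beta or se are dropped with a logged count; alleles
    are uppercased.
    """
    if kind not in ("gwas", "eqtl"):
        raise ValueError(f"kind must be 'gwas' or 'eqtl', got {kind!r}")
    df = pd.read_csv(path, sep=sep)
    required = ["snp", "effect_allele", "other_allele", "beta", "se", "p"]
    if kind == "eqtl":
        required.append("gene")
    missing = [c for c in required if c not in column_map]
    if missing:
        raise ValueError(f"column_map missing required keys: {missing}")
    absent = [column_map[c] for c in column_map if column_map[c] not in df.columns]
    if absent:
        raise ValueError(f"mapped columns absent from {path}: {absent}")

    def col(c):
        return df[column_map[c]]

    keep = col("beta").notna() & col("se").notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_summary_stats: dropped %d rows with missing beta/se", n_dropped)
    df = df.loc[keep]

    records: list = []
    for _, row in df.iterrows():
        se = float(row[column_map["se"]])
        if se <= 0:
            raise ValueError(f"{row[column_map['snp']]}: se <= 0")
        variant = VariantInfo(
            snp_id=str(row[column_map["snp"]]),
            chrom=str(row[column_map["chrom"]]) if "chrom" in column_map else "NA",
            pos=int(row[column_map["pos"]]) if "pos" in column_map else 1,
            effect_allele=str(row[column_map["effect_allele"]]).upper(),
            other_allele=str(row[column_map["other_allele"]]).upper(),
        )
        beta = float(row[column_map["beta"]])
        p = float(row[column_map["p"]])
        if kind == "eqtl":
            records.append(EQTLRecord(variant, str(row[column_map["gene"]]), beta, se, p))
        else:
            eaf = float(row[column_map["eaf"]]) if "eaf" in column_map and pd.notna(row[column_map["eaf"]]) else None
            n = float(row[column_map["n"]]) if "n" in column_map and pd.notna(row[column_map["n"]]) else None
            records.append(GWASSummaryRecord(variant, beta, se, p, eaf=eaf, n=n))
    return records


def write_summary_stats(records: Sequence[EQTLRecord | GWASSummaryRecord],
                        path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "snp": r.snp.snp_id, "chrom": r.snp.chrom, "pos": r.snp.pos,
            "effect_allele": r.snp.effect_allele, "other_allele": r.snp.other_allele,
            "beta": r.beta, "se": r.se, "p": r.p,
        }
        if isinstance(r, EQTLRecord):
            row["gene"] = r.gene_id
        else:
            row["eaf"] = r.eaf
            row["n"] = r.n
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_dosages(dosage_path: str | Path, variant_path: str | Path) -> GenotypeMatrix:
    """Read a sample x SNP dosage TSV plus its variant metadata table.

    The dosage file has sample ids in the first column and SNP ids in the
    header; the variant table has columns snp, chrom, pos, effect_allele,
    other_allele.  Empty cells are missing calls.
    """
    dos = pd.read_csv(dosage_path, sep="\t", index_col=0)
    var = pd.read_csv(variant_path, sep="\t", dtype={"chrom": str})
    meta = {str(r.snp): VariantInfo(str(r.snp), str(r.chrom), int(r.pos),
                                    str(r.effect_allele), str(r.other_allele))
            for r in var.itertuples()}
    missing = [s for s in dos.columns if str(s) not in meta]
    if missing:
        raise ValueError(f"variants absent from metadata table: {missing[:5]}")
    variants = [meta[str(s)] for s in dos.columns]
    return GenotypeMatrix(list(dos.index.astype(str)), variants,
                          dos.to_numpy(dtype=float))


def write_dosages(geno: GenotypeMatrix, dosage_path: str | Path,
                  variant_path: str | Path) -> None:
    df = pd.DataFrame(geno.dosages, index=geno.sample_ids, columns=geno.snp_ids)
    df.index.name = "sample_id"
    df.to_csv(dosage_path, sep="\t", float_format="%.10g")
    pd.DataFrame(
        [{"snp": v.snp_id, "chrom": v.chrom, "pos": v.pos,
          "effect_allele": v.effect_allele, "other_allele": v.other_allele}
         for v in geno.variants]
    ).to_csv(variant_path, sep="\t", index=False)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read dosages from a minimal VCF (DS format field preferred, else GT).

    Multi-allelic records are skipped with a warning.  Phasing is ignored.
    """
    from cyvcf2 import VCF  # optional dependency, only needed for VCF input

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantInfo] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning("skipping multi-allelic record %s", rec.ID or rec.POS)
            continue
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gts = rec.genotype.array()[:, :2]
            col = np.where((gts < 0).any(axis=1), np.nan,
                           gts.clip(min=0).sum(axis=1)).astype(float)
        snp_id = rec.ID or f"{rec.CHROM}:{rec.POS}"
        variants.append(VariantInfo(snp_id, str(rec.CHROM), int(rec.POS),
                                    str(rec.ALT[0]), str(rec.REF)))
        columns.append(col)
    if not variants:
        raise ValueError(f"no biallelic records in {path}")
    return GenotypeMatrix(samples, variants, np.column_stack(columns))


def write_table(df: pd.DataFrame, path: str | Path,
                sidecar: Mapping | None = None) -> None:
    """Write a results TSV (6 significant digits) plus a JSON provenance sidecar."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    if sidecar is not None:
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2, default=str)


def _first_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            return i
        seen.add(i)
    return None
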