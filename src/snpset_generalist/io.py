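"""Genotype and phenotype containers plus readers/writers for the supported
text dialects.

Genotypes travel as a :class:`GenotypeMatrix`: a rectangular individuals x SNPs
array of unphased allele-pair calls (two characters from A/C/G/T, e.g. ``"AG"``)
with ``"NN"`` as the missing sentinel, alongside per-SNP metadata
(:class:`SnpInfo`).  Three dialects are supported:

* PLINK text ``.ped``/``.map`` (missing call ``0 0``),
* VCF v4.2 with GT fields only (missing ``./.``),
* a simple TSV with one two-letter call column per SNP (missing ``NN``).

Increaser alleles and plex labels are not representable in ped/map or VCF, so
readers take a panel-metadata table carrying them.

Phenotypes travel as a :class:`PhenotypeTable` wrapping a pandas DataFrame:
a ``sex`` column (0/1), per-measure-group age-at-testing columns (named
``age_<measure>``) and real-valued measure columns with NaN for missing.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

MISSING_CALL = "NN"
VALID_ALLELES = frozenset("ACGT")

PANEL_COLUMNS = ["snp_id", "chrom", "pos", "allele_a", "allele_b",
                 "increaser_allele", "plex"]


@dataclass(frozen=True)
class SnpInfo:
    """Metadata for one biallelic SNP.

    ``increaser_allele`` is the allele associated with higher trait values in
    the discovery stage; it orients the additive 0/1/2 coding.  ``plex`` is the
    genotyping assay batch the SNP was typed in (missingness clusters within
    plexes).
    """

    snp_id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    increaser_allele: str
    plex: str

    def __post_init__(self) -> None:
        if self.allele_a not in VALID_ALLELES or self.allele_b not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: alleles must be one of A/C/G/T, "
                f"got {self.allele_a!r}/{self.allele_b!r}")
        if self.allele_a == self.allele_b:
            raise ValidationError(f"{self.snp_id}: alleles must differ")
        if self.increaser_allele not in (self.allele_a, self.allele_b):
            raise ValidationError(
                f"{self.snp_id}: increaser allele {self.increaser_allele!r} "
                f"not among declared alleles")
        if not self.plex:
            raise ValidationError(f"{self.snp_id}: empty plex label")
        if self.pos < 1:
            raise ValidationError(f"{self.snp_id}: position must be 1-based")


@dataclass
class GenotypeMatrix:
    """Rectangular individuals x SNPs matrix of allele-pair calls."""

    individual_ids: list[str]
    snps: list[SnpInfo]
    calls: np.ndarray  # (n_individuals, n_snps), dtype <U2, "NN" = missing

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="<U2")
        if self.calls.shape != (len(self.individual_ids), len(self.snps)):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.snps)} SNPs")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValidationError("duplicate individual IDs")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate SNP IDs")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in matrix") from None

    def validate_calls(self) -> None:
        """Check every non-missing call uses only its SNP's declared alleles."""
        for j, snp in enumerate(self.snps):
            col = self.calls[:, j]
            valid = _call_universe(snp)
            bad = ~np.isin(col, list(valid))
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"individual {self.individual_ids[i]!r}, SNP {snp.snp_id!r}: "
                    f"call {col[i]!r} uses alleles outside "
                    f"{snp.allele_a}/{snp.allele_b}")

    def subset(self, individuals=None, snps=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given individual IDs and/or
        SNP IDs (order preserved as given)."""
        if individuals is None:
            row_idx = np.arange(self.n_individuals)
            ids = list(self.individual_ids)
        else:
            pos = {iid: i for i, iid in enumerate(self.individual_ids)}
            row_idx = np.array([pos[i] for i in individuals], dtype=int)
            ids = list(individuals)
        if snps is None:
            col_idx = np.arange(self.n_snps)
            infos = list(self.snps)
        else:
            pos = {sid: j for j, sid in enumerate(self.snp_ids)}
            col_idx = np.array([pos[s] for s in snps], dtype=int)
            infos = [self.snps[j] for j in col_idx]
        calls = self.calls[np.ix_(row_idx, col_idx)] if len(row_idx) and len(col_idx) \
            else np.empty((len(row_idx), len(col_idx)), dtype="<U2")
        return GenotypeMatrix(ids, infos, calls.copy())

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.individual_ids), list(self.snps),
                              self.calls.copy())

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING_CALL

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (self.individual_ids == other.individual_ids
                and self.snps == other.snps
                and bool(np.array_equal(self.calls, other.calls)))


def _call_universe(snp: SnpInfo) -> set[str]:
    a, b = snp.allele_a, snp.allele_b
    return {a + a, a + b, b + a, b + b, MISSING_CALL}


@dataclass
class PhenotypeTable:
    """Cohort phenotypes: sex, per-measure ages-at-testing and trait scores.

    ``data`` is indexed by individual ID and holds a ``sex`` column (0/1),
    optional ``age_<measure>`` columns (years) and one float column per
    measure with NaN for missing.  ``age_by_measure`` maps each measure to its
    age column where one exists.
    """

    data: pd.DataFrame
    measures: list[str] = field(default_factory=list)
    age_by_measure: dict[str, str] = field(default_factory=dict)
    sex_col: str = "sex"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate individual ID {dup!r}")
        if not self.measures:
            self.measures = [c for c in self.data.columns
                             if c != self.sex_col and not c.startswith("age_")]
        if not self.age_by_measure:
            self.age_by_measure = {m: f"age_{m}" for m in self.measures
                                   if f"age_{m}" in self.data.columns}
        if self.sex_col in self.data.columns:
            sex = self.data[self.sex_col].dropna()
            if not sex.isin([0, 1]).all():
                raise ValidationError("sex must be coded 0/1")
        for m, c in self.age_by_measure.items():
            ages = self.data[c].dropna()
            if (ages <= 0).any():
                raise ValidationError(f"non-positive age in column {c!r}")

    @property
    def individual_ids(self) -> list[str]:
        return list(self.data.index)

    def measure(self, label: str) -> pd.Series:
        if label not in self.data.columns:
            raise KeyError(f"measure {label!r} not in table")
        return self.data[label]

    def sex(self) -> pd.Series:
        return self.data[self.sex_col]

    def age_for(self, measure: str) -> pd.Series | None:
        col = self.age_by_measure.get(measure)
        return self.data[col] if col is not None else None

    def copy(self) -> "PhenotypeTable":
        return PhenotypeTable(self.data.copy(), list(self.measures),
                              dict(self.age_by_measure), self.sex_col)


# ---------------------------------------------------------------------------
# Panel metadata

def read_panel(path) -> list[SnpInfo]:
    """Read SNP panel metadata from a TSV with columns snp_id, chrom, pos,
    allele_a, allele_b, increaser_allele, plex."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"panel file {path} lacks columns {missing}")
    return [SnpInfo(r.snp_id, r.chrom, int(r.pos), r.allele_a, r.allele_b,
                    r.increaser_allele, r.plex)
            for r in df.itertuples(index=False)]


def write_panel(snps: list[SnpInfo], path) -> None:
    df = pd.DataFrame([{c: getattr(s, c) for c in PANEL_COLUMNS} for s in snps])
    df.to_csv(path, sep="\t", index=False)


def _panel_by_id(panel) -> dict[str, SnpInfo]:
    if panel is None:
        raise ValidationError("panel metadata required (increaser alleles and "
                              "plex labels are not representable in ped/map or VCF)")
    import os

    if isinstance(panel, (str, bytes, os.PathLike)) or hasattr(panel, "read"):
        panel = read_panel(panel)
    return {s.snp_id: s for s in panel}


# ---------------------------------------------------------------------------
# Genotype readers

def read_genotypes(path, format: str, panel=None) -> GenotypeMatrix:
    """Read genotypes from ``path`` in the named dialect.

    ``panel`` (a list of :class:`SnpInfo` or a panel TSV path) supplies
    increaser alleles and plex labels; for ped/map and VCF it is merged by
    SNP id, for the TSV dialect it also defines the column order's metadata.
    """
    if format == "pedmap":
        return _read_pedmap(path, panel)
    if format == "vcf":
        return _read_vcf(path, panel)
    if format == "tsv":
        return _read_tsv_genotypes(path, panel)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(gm: GenotypeMatrix, path, format: str) -> None:
    """Write ``gm`` in the named dialect with deterministic row/column order."""
    if format == "pedmap":
        _write_pedmap(gm, path)
    elif format == "vcf":
        _write_vcf(gm, path)
    elif format == "tsv":
        _write_tsv_genotypes(gm, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _pedmap_paths(path):
    p = str(path)
    if p.endswith(".ped") or p.endswith(".map"):
        p = p[:-4]
    return p + ".ped", p + ".map"


def _read_pedmap(path, panel) -> GenotypeMatrix:
    ped_path, map_path = _pedmap_paths(path)
    meta = _panel_by_id(panel)
    snps: list[SnpInfo] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 columns, "
                                 f"got {len(parts)}")
            chrom, snp_id, _cm, pos = parts[:4]
            if snp_id not in meta:
                raise ValidationError(f"{map_path}:{lineno}: SNP {snp_id!r} "
                                      f"missing from panel metadata")
            m = meta[snp_id]
            snps.append(replace(m, chrom=chrom, pos=int(pos)))

    ids, rows = [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * len(snps):
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * len(snps)} "
                    f"columns, got {len(parts)}")
            ids.append(parts[1])
            alleles = parts[6:]
            row = []
            for j in range(len(snps)):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                if a == "0" or b == "0":
                    row.append(MISSING_CALL)
                else:
                    row.append(a + b)
            rows.append(row)
    calls = (np.array(rows, dtype="<U2") if rows
             else np.empty((0, len(snps)), dtype="<U2"))
    gm = GenotypeMatrix(ids, snps, calls)
    gm.validate_calls()
    return gm


def _write_pedmap(gm: GenotypeMatrix, path) -> None:
    ped_path, map_path = _pedmap_paths(path)
    with open(map_path, "w") as fh:
        for s in gm.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos}\n")
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(gm.individual_ids):
            fields = [iid, iid, "0", "0", "0", "-9"]
            for call in gm.calls[i]:
                if call == MISSING_CALL:
                    fields += ["0", "0"]
                else:
                    fields += [call[0], call[1]]
            fh.write(" ".join(fields) + "\n")


def _read_vcf(path, panel) -> GenotypeMatrix:
    from cyvcf2 import VCF

    meta = _panel_by_id(panel)
    vcf = VCF(str(path))
    ids = list(vcf.samples)
    snps, cols = [], []
    for variant in vcf:
        snp_id = variant.ID
        if snp_id is None or snp_id not in meta:
            raise ValidationError(f"VCF record at {variant.CHROM}:{variant.POS} "
                                  f"has ID {snp_id!r} not in panel metadata")
        ref = variant.REF
        alts = variant.ALT
        if len(alts) != 1:
            raise ParseError(f"{snp_id}: multi-allelic records not supported")
        alt = alts[0]
        m = meta[snp_id]
        if {ref, alt} != {m.allele_a, m.allele_b}:
            raise ValidationError(
                f"{snp_id}: VCF alleles {ref}/{alt} disagree with panel "
                f"{m.allele_a}/{m.allele_b}")
        snps.append(replace(m, chrom=str(variant.CHROM), pos=int(variant.POS),
                            allele_a=ref, allele_b=alt))
        col = []
        for g in variant.genotypes:
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                col.append(MISSING_CALL)
            else:
                allele = (ref, alt)
                col.append(allele[a0] + allele[a1])
        cols.append(col)
    vcf.close()
    calls = (np.array(cols, dtype="<U2").T if cols
             else np.empty((len(ids), 0), dtype="<U2"))
    gm = GenotypeMatrix(ids, snps, calls)
    gm.validate_calls()
    return gm


def _write_vcf(gm: GenotypeMatrix, path) -> None:
    buf = _stdio.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
              + "\t".join(gm.individual_ids) + "\n")
    for j, s in enumerate(gm.snps):
        ref, alt = s.allele_a, s.allele_b
        gts = []
        for call in gm.calls[:, j]:
            if call == MISSING_CALL:
                gts.append("./.")
            else:
                idx = sorted("01"[c == alt] for c in call)
                gts.append("/".join(idx))
        buf.write(f"{s.chrom}\t{s.pos}\t{s.snp_id}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                  + "\t".join(gts) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _read_tsv_genotypes(path, panel) -> GenotypeMatrix:
    meta = _panel_by_id(panel)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "individual_id":
        raise ParseError(f"{path}: first column must be 'individual_id'")
    snp_ids = list(df.columns[1:])
    unknown = [s for s in snp_ids if s not in meta]
    if unknown:
        raise ValidationError(f"{path}: SNPs {unknown} missing from panel metadata")
    ids = list(df["individual_id"])
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate individual IDs")
    calls = df[snp_ids].to_numpy(dtype="<U2") if snp_ids else \
        np.empty((len(ids), 0), dtype="<U2")
    gm = GenotypeMatrix(ids, [meta[s] for s in snp_ids], calls)
    gm.validate_calls()
    return gm


def _write_tsv_genotypes(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(gm.calls, columns=gm.snp_ids)
    df.insert(0, "individual_id", gm.individual_ids)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phenotypes

def read_phenotypes(path) -> PhenotypeTable:
    """Read a phenotype TSV: ``individual_id``, ``sex``, optional ``age_*``
    columns, one column per measure.  Blank cells and ``NA`` are missing."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str},
                     na_values=["NA", ""], keep_default_na=False)
    if "individual_id" not in df.columns:
        raise ParseError(f"{path}: missing 'individual_id' column")
    df = df.set_index("individual_id")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate individual ID {dup!r}")
    for col in df.columns:
        if col == "sex":
            continue
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                          & df[col].notna()]
            raise ParseError(
                f"{path}: non-numeric value {bad.iloc[0]!r} in column "
                f"{col!r}, individual {bad.index[0]!r}") from exc
    if "sex" in df.columns:
        df["sex"] = pd.to_numeric(df["sex"])
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path) -> None:
    table.data.to_csv(path, sep="\t", na_rep="NA", index_label="individual_id")


def write_association_report(rows: pd.DataFrame, path) -> None:
    """Write an association report CSV (one row per predictor x measure)."""
    rows.to_csv(path, index=False)
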