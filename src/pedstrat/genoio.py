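"""Genotype and pedigree containers, PLINK-text / VCF I/O, allele frequencies,
and the data-cleaning filters (MAF, Mendelian consistency).

Conventions
-----------
* Dosage counts copies of the **alternate** allele declared in the variant
  metadata, identically in every group of individuals.  Per-group minor-allele
  flipping is never performed: a between-group frequency difference is only
  well defined when both groups refer to the same allele.
* Missing genotypes are ``NaN`` in the dosage matrix and are dropped from both
  numerator and denominator of every frequency (no imputation).
* Coordinates are 1-based, as in VCF and PLINK MAP files.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "DataError",
    "Pedigree",
    "GenotypeMatrix",
    "read_genotypes",
    "write_genotypes",
    "read_ped_map",
    "write_ped_map",
    "read_vcf",
    "write_vcf",
    "compute_freq",
    "filter_maf",
    "mendel_check",
    "filter_mendel",
    "write_freq_table",
]

MISSING_PARENT = "0"


class ParseError(ValueError):
    """A file does not parse under the named standard."""


class DataError(ValueError):
    """Parsed content violates a data contract (e.g. unknown allele)."""


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """Family structure: one row per individual.

    ``table`` columns: ``fid, iid, father, mother, sex, founder`` where
    ``father``/``mother`` are ``"0"`` for founders, ``sex`` is 1=male /
    2=female (PLINK coding) and ``founder`` is a boolean.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["fid", "iid", "father", "mother", "sex", "founder"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise DataError(f"pedigree table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    # -- accessors ---------------------------------------------------------
    @property
    def iids(self) -> list[str]:
        return self.table["iid"].tolist()

    @property
    def fids(self) -> list[str]:
        return sorted(self.table["fid"].unique().tolist())

    def members(self, fid: str) -> list[str]:
        return self.table.loc[self.table["fid"] == fid, "iid"].tolist()

    def family_sizes(self) -> pd.Series:
        return self.table.groupby("fid").size()

    def family_of(self) -> pd.Series:
        """Map iid -> fid."""
        return self.table.set_index("iid")["fid"]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        t = self.table
        if t["iid"].duplicated().any():
            dup = t.loc[t["iid"].duplicated(), "iid"].iloc[0]
            raise DataError(f"duplicate individual id: {dup}")
        by_iid = t.set_index("iid")
        nonf = t[~t["founder"]]
        for col in ("father", "mother"):
            pids = nonf[col]
            if (pids == MISSING_PARENT).any():
                raise DataError("non-founder with absent parent id")
            unknown = set(pids) - set(t["iid"])
            if unknown:
                raise DataError(f"parent ids not in pedigree: {sorted(unknown)[:5]}")
            pfam = by_iid.loc[pids, "fid"].to_numpy()
            if (pfam != nonf["fid"].to_numpy()).any():
                raise DataError("parent recorded in a different family")
        founders = t[t["founder"]]
        if ((founders["father"] != MISSING_PARENT) | (founders["mother"] != MISSING_PARENT)).any():
            raise DataError("founder with a parent id")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = {
            r.iid: [p for p in (r.father, r.mother) if p != MISSING_PARENT]
            for r in self.table.itertuples()
        }
        state: dict[str, int] = {}  # 0=in progress, 1=done

        for start in parents:
            if start in state:
                continue
            stack = [(start, iter(parents[start]))]
            state[start] = 0
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if p not in parents:
                        continue
                    s = state.get(p)
                    if s == 0:
                        raise DataError(f"pedigree cycle through {p!r}")
                    if s is None:
                        state[p] = 0
                        stack.append((p, iter(parents[p])))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 1
                    stack.pop()

    def topological_order(self) -> list[str]:
        """Individual ids with every parent preceding its children."""
        t = self.table
        order: list[str] = []
        placed: set[str] = set()
        pending = list(t.itertuples())
        while pending:
            rest = []
            for r in pending:
                ok = all(
                    p == MISSING_PARENT or p in placed
                    for p in (r.father, r.mother)
                )
                if ok:
                    order.append(r.iid)
                    placed.add(r.iid)
                else:
                    rest.append(r)
            if len(rest) == len(pending):
                raise DataError("pedigree is not acyclic or has missing parents")
            pending = rest
        return order

    # -- FAM I/O -----------------------------------------------------------
    @classmethod
    def read_fam(cls, path: str | Path) -> "Pedigree":
        rows = []
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ParseError(f"{path}:{ln}: FAM line has {len(parts)} fields, need >=5")
            fid, iid, fa, mo, sex = parts[:5]
            rows.append((fid, iid, fa, mo, int(sex)))
        df = pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex"])
        df["founder"] = (df["father"] == MISSING_PARENT) & (df["mother"] == MISSING_PARENT)
        return cls(df)

    def write_fam(self, path: str | Path, phenotype: Mapping[str, float] | None = None) -> None:
        with open(path, "w") as fh:
            for r in self.table.itertuples():
                ph = phenotype.get(r.iid, -9) if phenotype else -9
                fh.write(f"{r.fid} {r.iid} {r.father} {r.mother} {r.sex} {ph}\n")


# ---------------------------------------------------------------------------
# GenotypeMatrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x variants additive dosage matrix with metadata.

    ``dosage`` is float with values in {0, 1, 2} and ``NaN`` for missing.
    ``variants`` columns: ``id, chrom, pos, ref, alt`` (unique ids);
    ``samples`` columns: ``fid, iid`` aligned to dosage rows.
    """

    dosage: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise DataError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.variants["id"].duplicated().any():
            raise DataError("duplicate variant ids")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = self.dosage[~ok].flat[0]
            raise DataError(f"dosage value {bad!r} not in {{0,1,2,NaN}}")
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["id"].tolist()

    @property
    def iids(self) -> list[str]:
        return self.samples["iid"].tolist()

    def variant_indexer(self, ids: Sequence[str]) -> np.ndarray:
        lookup = pd.Index(self.variants["id"])
        idx = lookup.get_indexer(list(ids))
        if (idx < 0).any():
            missing = [v for v, i in zip(ids, idx) if i < 0]
            raise DataError(f"unknown variant ids: {missing[:5]}")
        return idx

    def subset_variants(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.variant_indexer(ids)
        return GenotypeMatrix(
            self.dosage[:, idx], self.variants.iloc[idx], self.samples.copy()
        )

    def subset_individuals(self, iids: Sequence[str]) -> "GenotypeMatrix":
        lookup = pd.Index(self.samples["iid"])
        idx = lookup.get_indexer(list(iids))
        if (idx < 0).any():
            missing = [v for v, i in zip(iids, idx) if i < 0]
            raise DataError(f"unknown individual ids: {missing[:5]}")
        return GenotypeMatrix(
            self.dosage[idx, :], self.variants.copy(), self.samples.iloc[idx]
        )

    def row_of(self, iid: str) -> int:
        idx = pd.Index(self.samples["iid"]).get_loc(iid)
        return int(idx)


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def write_ped_map(
    matrix: GenotypeMatrix,
    prefix: str | Path,
    pedigree: Pedigree | None = None,
    phenotype: Mapping[str, float] | None = None,
) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` and an extended ``<prefix>.map``.

    The MAP file carries two extra trailing columns (ref, alt) so that the
    alternate-allele orientation survives a round trip; a standard 4-column
    MAP cannot represent it.
    """
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")

    with open(map_path, "w") as fh:
        for v in matrix.variants.itertuples():
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.ref}\t{v.alt}\n")

    ped_info = pedigree.table.set_index("iid") if pedigree is not None else None
    ref = matrix.variants["ref"].to_numpy()
    alt = matrix.variants["alt"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, s in enumerate(matrix.samples.itertuples()):
            if ped_info is not None and s.iid in ped_info.index:
                r = ped_info.loc[s.iid]
                fa, mo, sex = r["father"], r["mother"], r["sex"]
            else:
                fa, mo, sex = MISSING_PARENT, MISSING_PARENT, 0
            ph = phenotype.get(s.iid, -9) if phenotype else -9
            row = matrix.dosage[i]
            pairs = []
            for j, d in enumerate(row):
                if np.isnan(d):
                    pairs.append("0 0")
                elif d == 0:
                    pairs.append(f"{ref[j]} {ref[j]}")
                elif d == 1:
                    pairs.append(f"{ref[j]} {alt[j]}")
                else:
                    pairs.append(f"{alt[j]} {alt[j]}")
            fh.write(f"{s.fid} {s.iid} {fa} {mo} {sex} {ph} " + " ".join(pairs) + "\n")
    return ped_path, map_path


def _read_map(path: Path) -> pd.DataFrame:
    rows = []
    extended = None
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) not in (4, 6):
            raise ParseError(f"{path}:{ln}: MAP line has {len(parts)} fields, need 4 or 6")
        if extended is None:
            extended = len(parts) == 6
        elif extended != (len(parts) == 6):
            raise ParseError(f"{path}:{ln}: mixed 4- and 6-column MAP lines")
        if extended:
            chrom, vid, _cm, pos, ref, alt = parts
        else:
            chrom, vid, _cm, pos = parts
            ref = alt = None
        rows.append((vid, chrom, int(pos), ref, alt))
    df = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])
    if df["id"].duplicated().any():
        raise ParseError(f"{path}: duplicate variant ids")
    return df


def read_ped_map(prefix: str | Path) -> tuple[GenotypeMatrix, Pedigree]:
    """Read ``<prefix>.ped`` + ``<prefix>.map`` into a dosage matrix and pedigree.

    With a 4-column MAP the alternate allele is unknown; it is then inferred
    as the minor allele observed in the file (with a warning), which may flip
    orientation relative to the writer.
    """
    prefix = Path(prefix)
    variants = _read_map(prefix.with_suffix(".map"))
    m = len(variants)
    infer_alleles = variants["ref"].isna().any()
    if infer_alleles:
        warnings.warn(
            "4-column MAP: alternate allele inferred as the observed minor allele",
            stacklevel=2,
        )

    sample_rows = []
    ped_rows = []
    allele_cols: list[np.ndarray] = []
    for ln, line in enumerate(prefix.with_suffix(".ped").read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise ParseError(
                f"{prefix.with_suffix('.ped')}:{ln}: expected {6 + 2 * m} fields, got {len(parts)}"
            )
        fid, iid, fa, mo, sex, _ph = parts[:6]
        sample_rows.append((fid, iid))
        ped_rows.append((fid, iid, fa, mo, int(sex)))
        allele_cols.append(np.array(parts[6:], dtype=object))
    alleles = (
        np.stack(allele_cols) if allele_cols else np.empty((0, 2 * m), dtype=object)
    )
    a1, a2 = alleles[:, 0::2], alleles[:, 1::2]

    if infer_alleles:
        ref_arr = np.empty(m, dtype=object)
        alt_arr = np.empty(m, dtype=object)
        for j in range(m):
            obs = [a for a in np.concatenate([a1[:, j], a2[:, j]]) if a != "0"]
            uniq, counts = np.unique(obs, return_counts=True) if obs else ([], [])
            if len(uniq) > 2:
                raise DataError(f"variant {variants['id'][j]}: more than two alleles observed")
            if len(uniq) == 0:
                ref_arr[j], alt_arr[j] = "A", "B"
            elif len(uniq) == 1:
                ref_arr[j], alt_arr[j] = uniq[0], "B"
            else:
                order = np.argsort(counts, kind="stable")
                alt_arr[j], ref_arr[j] = uniq[order[0]], uniq[order[1]]
        variants = variants.assign(ref=ref_arr, alt=alt_arr)

    ref = variants["ref"].to_numpy()
    alt = variants["alt"].to_numpy()
    n = alleles.shape[0]
    dosage = np.full((n, m), np.nan)
    for j in range(m):
        col1, col2 = a1[:, j], a2[:, j]
        known = {ref[j], alt[j], "0"}
        bad = {b for b in (set(col1) | set(col2)) if b not in known}
        if bad:
            raise DataError(
                f"variant {variants['id'][j]}: allele {sorted(bad)[0]!r} not in "
                f"declared pair ({ref[j]},{alt[j]})"
            )
        miss = (col1 == "0") | (col2 == "0")
        dosage[:, j] = (col1 == alt[j]).astype(float) + (col2 == alt[j]).astype(float)
        dosage[miss, j] = np.nan

    samples = pd.DataFrame(sample_rows, columns=["fid", "iid"])
    peddf = pd.DataFrame(ped_rows, columns=["fid", "iid", "father", "mother", "sex"])
    peddf["founder"] = (peddf["father"] == MISSING_PARENT) & (peddf["mother"] == MISSING_PARENT)
    return GenotypeMatrix(dosage, variants, samples), Pedigree(peddf)


# ---------------------------------------------------------------------------
# VCF v4.2 (GT only)
# ---------------------------------------------------------------------------

def write_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    seed: int | None = None,
) -> Path:
    path = Path(path)
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pedstrat\n")
        if seed is not None:
            fh.write(f"##pedstrat_seed={seed}\n")
        for chrom in matrix.variants["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.iids)
            + "\n"
        )
        for j, v in enumerate(matrix.variants.itertuples()):
            gts = "\t".join(
                gt_of.get(d, "./.") for d in matrix.dosage[:, j]
            )
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")
    return path


def read_vcf(path: str | Path, fids: Mapping[str, str] | None = None) -> GenotypeMatrix:
    """Read GT fields from a (plain-text or bgzipped) VCF via cyvcf2.

    ``fids`` optionally maps sample id -> family id; unknown samples get
    fid ``"0"``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    iids = list(vcf.samples)
    rows = []
    cols = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise DataError(f"variant {var.ID or var.POS}: only biallelic records supported")
        gt = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        d = np.where(gt == 3, 2.0, gt)
        d[gt == 2] = np.nan
        cols.append(d)
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS, var.REF, var.ALT[0]))
    variants = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])
    dosage = np.column_stack(cols) if cols else np.empty((len(iids), 0))
    samples = pd.DataFrame(
        {"fid": [fids.get(i, "0") if fids else "0" for i in iids], "iid": iids}
    )
    return GenotypeMatrix(dosage, variants, samples)


def read_genotypes(path: str | Path, format: str) -> GenotypeMatrix:
    if format == "ped_map":
        return read_ped_map(path)[0]
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown format {format!r}")


def write_genotypes(
    matrix: GenotypeMatrix,
    path: str | Path,
    format: str,
    pedigree: Pedigree | None = None,
) -> None:
    if format == "ped_map":
        write_ped_map(matrix, path, pedigree=pedigree)
    elif format == "vcf":
        write_vcf(matrix, path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def compute_freq(
    matrix: GenotypeMatrix,
    grouping: Mapping[str, str] | pd.Series | None = None,
) -> pd.DataFrame:
    """Per-variant, per-group alternate-allele frequency table.

    Columns: ``variant_id, group, p_alt, maf, n_alleles``.  ``p_alt`` is the
    count of alternate alleles over non-missing alleles; it is ``NaN`` (not 0)
    for a group with no non-missing calls at a variant.
    """
    if grouping is None:
        labels = pd.Series("all", index=matrix.samples["iid"])
    elif isinstance(grouping, pd.Series):
        labels = grouping
    else:
        labels = pd.Series(dict(grouping))
    missing = set(labels.index) - set(matrix.iids)
    if missing:
        raise DataError(f"grouped individuals not in matrix: {sorted(missing)[:5]}")

    frames = []
    iid_index = pd.Index(matrix.samples["iid"])
    for group in sorted(labels.unique()):
        members = labels.index[labels == group]
        idx = iid_index.get_indexer(members)
        sub = matrix.dosage[idx, :]
        nonmiss = (~np.isnan(sub)).sum(axis=0)
        n_alleles = 2 * nonmiss
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(sub, axis=0) / n_alleles
        p = np.where(n_alleles == 0, np.nan, p)
        maf = np.minimum(p, 1.0 - p)
        frames.append(
            pd.DataFrame(
                {
                    "variant_id": matrix.variant_ids,
                    "group": group,
                    "p_alt": p,
                    "maf": maf,
                    "n_alleles": n_alleles,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_freq_table(table: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        table.to_csv(fh, sep="\t", index=False)


def filter_maf(
    matrix: GenotypeMatrix,
    table: pd.DataFrame | None = None,
    threshold: float = 0.1,
) -> GenotypeMatrix:
    """Keep exactly the variants with whole-sample MAF strictly > threshold."""
    if table is None:
        table = compute_freq(matrix)
    whole = table[table["group"] == "all"] if "group" in table else table
    maf = whole.set_index("variant_id")["maf"].reindex(matrix.variant_ids)
    keep = [v for v, m in zip(matrix.variant_ids, maf) if np.isfinite(m) and m > threshold]
    return matrix.subset_variants(keep)


# ---------------------------------------------------------------------------
# Mendelian consistency
# ---------------------------------------------------------------------------

def mendel_check(matrix: GenotypeMatrix, pedigree: Pedigree) -> pd.DataFrame:
    """Flag (individual, variant) dosage combinations impossible under
    Mendelian transmission from the recorded parents.

    A parent with dosage 0 can transmit only the reference allele, dosage 2
    only the alternate, dosage 1 either; a missing parent genotype
    constrains nothing.  The child dosage must lie in the interval spanned by
    the minimal and maximal transmissible allele counts.
    """
    iid_row = {iid: i for i, iid in enumerate(matrix.iids)}
    violations = []
    vids = np.asarray(matrix.variant_ids)
    for r in pedigree.table.itertuples():
        if r.founder or r.iid not in iid_row:
            continue
        child = matrix.dosage[iid_row[r.iid]]

        def bounds(pid: str) -> tuple[np.ndarray, np.ndarray]:
            if pid == MISSING_PARENT or pid not in iid_row:
                return np.zeros_like(child), np.ones_like(child)
            d = matrix.dosage[iid_row[pid]]
            lo = np.where(np.isnan(d), 0.0, (d == 2).astype(float))
            hi = np.where(np.isnan(d), 1.0, (d > 0).astype(float))
            return lo, hi

        flo, fhi = bounds(r.father)
        mlo, mhi = bounds(r.mother)
        bad = (~np.isnan(child)) & ((child < flo + mlo) | (child > fhi + mhi))
        for j in np.flatnonzero(bad):
            violations.append((r.iid, vids[j]))
    return pd.DataFrame(violations, columns=["iid", "variant_id"])


def filter_mendel(
    matrix: GenotypeMatrix,
    violations: pd.DataFrame,
    max_violations: int = 0,
) -> GenotypeMatrix:
    """Drop variants with more than ``max_violations`` Mendelian errors
    (default: any error removes the variant)."""
    counts = violations.groupby("variant_id").size() if len(violations) else pd.Series(dtype=int)
    keep = [v for v in matrix.variant_ids if counts.get(v, 0) <= max_violations]
    return matrix.subset_variants(keep)
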