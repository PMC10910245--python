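"""Reading, writing and aligning cohort genotype/phenotype files.

Supported genotype dialects are the PLINK 1.x text formats:

``raw``
    Whitespace-delimited additive dosage export (``plink --recode A``):
    header row ``FID IID PAT MAT SEX PHENOTYPE`` followed by one column
    per SNP named ``<snp_id>_<counted_allele>``; entries 0/1/2 or ``NA``.
    Full SNP metadata (chromosome, position, reference allele) is carried
    in a sidecar ``<stem>.snps.tsv`` written by :func:`write_genotypes`;
    absent a sidecar, placeholder metadata is synthesized.
``ped_map``
    ``.ped`` (two allele letters per SNP) plus ``.map`` (chrom, id, cM,
    bp).  Dosages count the minor allele (ties broken lexicographically).

Records with non-ACGT or haploid allele calls are excluded, counted and
logged rather than imputed or guessed.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from .types import MISSING, CohortAlignment, DatasetSplit, GenotypeMatrix, PhenotypeTable, SnpMeta

logger = logging.getLogger(__name__)

_RAW_LEAD_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
_VALID_ALLELES = frozenset("ACGT")


class ParseError(ValueError):
    """Malformed input file; message carries the offending location."""


def read_genotypes(path: str | Path, format: str = "raw") -> GenotypeMatrix:
    """Read a genotype matrix from a PLINK-style text file.

    Parameters
    ----------
    path
        The ``.raw`` file, or either member of a ``.ped``/``.map`` pair.
    format
        ``"raw"`` or ``"ped_map"``.
    """
    path = Path(path)
    if format == "raw":
        return _read_raw(path)
    if format == "ped_map":
        return _read_ped_map(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_raw(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep=r"\s+", dtype=str, na_values=["NA"])
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse .raw file: {exc}") from exc
    missing_lead = [c for c in _RAW_LEAD_COLS if c not in df.columns]
    if missing_lead:
        raise ParseError(f"{path}: .raw header lacks columns {missing_lead}")
    sample_ids = df["IID"].astype(str).tolist()
    geno_cols = [c for c in df.columns if c not in _RAW_LEAD_COLS]

    sidecar = _read_snp_sidecar(path)
    snps: list[SnpMeta] = []
    cols: list[np.ndarray] = []
    n_excluded = 0
    for j, col in enumerate(geno_cols):
        snp_id, _, counted = col.rpartition("_")
        if not snp_id or counted not in _VALID_ALLELES:
            n_excluded += 1
            logger.warning("excluding SNP column %r: counted allele is not ACGT", col)
            continue
        raw = df[col]
        values = np.full(len(raw), MISSING, dtype=np.int16)
        obs = raw.notna()
        try:
            numeric = raw[obs].astype(float)
        except ValueError as exc:
            bad = raw[obs][pd.to_numeric(raw[obs], errors="coerce").isna()]
            line = bad.index[0] + 2  # 1-based + header
            raise ParseError(f"{path}:{line}: non-numeric dosage {bad.iloc[0]!r}") from exc
        if not numeric.isin([0.0, 1.0, 2.0]).all():
            bad = numeric[~numeric.isin([0.0, 1.0, 2.0])]
            raise ParseError(f"{path}:{bad.index[0] + 2}: dosage {bad.iloc[0]} not in 0/1/2")
        values[obs.to_numpy()] = numeric.to_numpy(dtype=np.int16)
        meta = sidecar.get(snp_id) if sidecar else None
        if meta is None:
            meta = SnpMeta(id=snp_id, chrom="0", pos_bp=j + 1, ref_allele="N", alt_allele=counted)
        cols.append(values)
        snps.append(meta)
    if n_excluded:
        logger.info("%s: excluded %d SNP record(s) with invalid alleles", path, n_excluded)
    values = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0), dtype=np.int16)
    return GenotypeMatrix(values=values, sample_ids=sample_ids, snps=snps)


def _read_snp_sidecar(raw_path: Path) -> dict[str, SnpMeta]:
    sidecar = raw_path.parent / (raw_path.stem + ".snps.tsv")
    if not sidecar.exists():
        return {}
    df = pd.read_csv(sidecar, sep="\t", dtype=str)
    out = {}
    for row in df.itertuples(index=False):
        out[row.id] = SnpMeta(
            id=row.id,
            chrom=str(row.chrom),
            pos_bp=int(row.pos_bp),
            ref_allele=row.ref_allele,
            alt_allele=row.alt_allele,
        )
    return out


def _read_ped_map(path: Path) -> GenotypeMatrix:
    path = Path(path)
    stem = path.with_suffix("")
    ped_path, map_path = stem.with_suffix(".ped"), stem.with_suffix(".map")
    for p in (ped_path, map_path):
        if not p.exists():
            raise FileNotFoundError(p)
    map_df = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["chrom", "id", "cm", "pos_bp"], dtype=str
    )
    n_snps = len(map_df)

    sample_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields, got {len(fields)}"
                )
            sample_ids.append(fields[1])
            allele_rows.append(fields[6:])
    alleles = np.array(allele_rows, dtype="U8") if allele_rows else np.empty((0, 2 * n_snps), "U1")

    cols: list[np.ndarray] = []
    snps: list[SnpMeta] = []
    n_excluded = 0
    for j in range(n_snps):
        a1, a2 = alleles[:, 2 * j], alleles[:, 2 * j + 1]
        miss = (a1 == "0") & (a2 == "0")
        haploid = ((a1 == "0") | (a2 == "0")) & ~miss
        observed = np.concatenate([a1[~miss], a2[~miss]])
        bad_letters = set(observed) - _VALID_ALLELES
        if haploid.any() or bad_letters:
            n_excluded += 1
            reason = "haploid call" if haploid.any() else f"non-ACGT alleles {sorted(bad_letters)}"
            logger.warning("excluding SNP %s: %s", map_df["id"].iloc[j], reason)
            continue
        counts = Counter(observed)
        if not counts:  # all missing: keep as fully-missing monomorphic record
            ref = alt = "N"
        else:
            # count the minor allele; ties broken lexicographically
            ordered = sorted(counts.items(), key=lambda kv: (kv[1], kv[0]))
            alt = ordered[0][0]
            ref = ordered[-1][0] if len(ordered) > 1 else alt
            if ref == alt and len(ordered) > 1:
                ref = ordered[-1][0]
        dosage = (a1 == alt).astype(np.int16) + (a2 == alt).astype(np.int16)
        dosage[miss] = MISSING
        cols.append(dosage)
        row = map_df.iloc[j]
        snps.append(
            SnpMeta(id=row["id"], chrom=str(row["chrom"]), pos_bp=int(row["pos_bp"]),
                    ref_allele=ref, alt_allele=alt)
        )
    if n_excluded:
        logger.info("%s: excluded %d SNP record(s)", ped_path, n_excluded)
    values = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0), dtype=np.int16)
    return GenotypeMatrix(values=values, sample_ids=sample_ids, snps=snps)


def write_genotypes(path: str | Path, G: GenotypeMatrix) -> None:
    """Write a ``.raw`` dosage file plus the ``<stem>.snps.tsv`` metadata
    sidecar so that :func:`read_genotypes` round-trips losslessly."""
    path = Path(path)
    with open(path, "w") as fh:
        header = _RAW_LEAD_COLS + [f"{s.id}_{s.alt_allele}" for s in G.snps]
        fh.write(" ".join(header) + "\n")
        for i, sid in enumerate(G.sample_ids):
            row = G.values[i]
            cells = ["NA" if v == MISSING else str(int(v)) for v in row]
            fh.write(" ".join([sid, sid, "0", "0", "0", "-9"] + cells) + "\n")
    meta = pd.DataFrame(
        [(s.id, s.chrom, s.pos_bp, s.ref_allele, s.alt_allele) for s in G.snps],
        columns=["id", "chrom", "pos_bp", "ref_allele", "alt_allele"],
    )
    meta.to_csv(path.parent / (path.stem + ".snps.tsv"), sep="\t", index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype table (TSV or CSV) with columns
    ``sample_id, status[, covariate...]``; status must be binary."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    for col in ("sample_id", "status"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    status_raw = pd.to_numeric(df["status"], errors="coerce")
    bad = status_raw.isna() | ~status_raw.isin([0, 1])
    if bad.any():
        i = int(bad.idxmax())
        raise ParseError(
            f"{path}: row {i + 2} (sample {df['sample_id'].iloc[i]!r}): "
            f"status {df['status'].iloc[i]!r} is not binary 0/1"
        )
    cov_cols = [c for c in df.columns if c not in ("sample_id", "status")]
    covariates = None
    if cov_cols:
        covariates = df[cov_cols].apply(pd.to_numeric).reset_index(drop=True)
    return PhenotypeTable(
        sample_ids=df["sample_id"].astype(str).tolist(),
        status=status_raw.astype(int).to_numpy(),
        covariates=covariates,
    )


def write_phenotypes(path: str | Path, P: PhenotypeTable) -> None:
    df = pd.DataFrame({"sample_id": P.sample_ids, "status": P.status})
    if P.covariates is not None:
        df = pd.concat([df, P.covariates.reset_index(drop=True)], axis=1)
    sep = "," if Path(path).suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False)


def align_cohort(
    G: GenotypeMatrix, P: PhenotypeTable
) -> tuple[GenotypeMatrix, PhenotypeTable, CohortAlignment]:
    """Row-align genotypes and phenotypes on their common sample ids.

    The common ids are ordered lexicographically (a fixed, deterministic
    ordering); samples present in only one source are dropped.  Raises if
    the id sets are disjoint.  Sample identity should not be consulted
    downstream of this point — row order is the contract.
    """
    g_index = {sid: i for i, sid in enumerate(G.sample_ids)}
    p_index = {sid: i for i, sid in enumerate(P.sample_ids)}
    common = sorted(set(g_index) & set(p_index))
    if not common:
        raise ValueError("genotype and phenotype sample id sets are disjoint")
    g_rows = [g_index[s] for s in common]
    p_rows = [p_index[s] for s in common]
    alignment = CohortAlignment(
        common_ids=tuple(common),
        genotype_row_index={s: g_index[s] for s in common},
        phenotype_row_index={s: p_index[s] for s in common},
    )
    return G.take_samples(g_rows), P.take(p_rows), alignment


def split_working_validation(
    status: np.ndarray, validation_fraction: float, rng_seed: int
) -> DatasetSplit:
    """Stratified working/validation split of sample rows.

    The draw is stratified by case/control so the held-out set preserves
    the cohort class balance.  Raises if either part would lack a class.
    """
    from .youden import _stratified_quotas

    status = np.asarray(status, dtype=int)
    if not 0.0 < validation_fraction < 1.0:
        raise ValueError("validation_fraction must be in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    quotas = _stratified_quotas(status, validation_fraction)
    val: list[int] = []
    work: list[int] = []
    for cls in (0, 1):
        idx = np.flatnonzero(status == cls)
        n_val = quotas[cls]
        if n_val < 1 or len(idx) - n_val < 1:
            raise ValueError(
                f"validation_fraction {validation_fraction} leaves class {cls} "
                "absent from one part"
            )
        perm = rng.permutation(idx)
        val.extend(perm[:n_val].tolist())
        work.extend(perm[n_val:].tolist())
    return DatasetSplit(
        working_indices=tuple(sorted(work)), validation_indices=tuple(sorted(val))
    )
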