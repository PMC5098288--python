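"""Genotype matrices and SNP quality control.

Genotypes are allele counts (0, 1 or 2 copies of the counted allele) for a
set of animals at a set of bi-allelic SNP markers, with missing entries
allowed.  Quality control follows the standard genomic-prediction recipe:

1. orient every marker to count the *minor* allele (:func:`recode_minor_allele`),
2. drop markers whose minor-allele frequency is below a threshold
   (:func:`filter_maf`, default 5%, strict "lower than"),
3. replace remaining missing entries by the rounded expected allele count
   ``round(2p)`` (:func:`impute_missing`, round-half-up).

Allele frequencies are always computed over non-missing entries only.
Missing entries are represented internally as ``NaN`` in a float array and
as ``NA`` in the on-disk TSV dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "AlleleFrequencies",
    "QCReport",
    "read_genotypes",
    "write_genotypes",
    "compute_allele_frequencies",
    "recode_minor_allele",
    "filter_maf",
    "impute_missing",
    "qc_pipeline",
]


class GenotypeError(ValueError):
    """Raised for malformed or inconsistent genotype data."""


@dataclass
class GenotypeMatrix:
    """Animals × markers matrix of allele counts with missing support.

    Parameters
    ----------
    animal_ids : array of str
        Unique animal identifiers, one per row.
    marker_ids : array of str
        Unique marker identifiers, one per column.
    values : ndarray of float, shape (n_animals, n_markers)
        Entries in {0, 1, 2} or NaN for missing.
    oriented_minor : bool
        True once :func:`recode_minor_allele` has run, i.e. every column
        counts the minor allele (frequency ≤ 0.5 on non-missing entries).
    """

    animal_ids: np.ndarray
    marker_ids: np.ndarray
    values: np.ndarray
    oriented_minor: bool = False

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GenotypeError("values must be a 2-D array")
        n, m = self.values.shape
        if len(self.animal_ids) != n:
            raise GenotypeError(
                f"{len(self.animal_ids)} animal ids for {n} genotype rows"
            )
        if len(self.marker_ids) != m:
            raise GenotypeError(
                f"{len(self.marker_ids)} marker ids for {m} genotype columns"
            )
        for name, ids in (("animal", self.animal_ids), ("marker", self.marker_ids)):
            if len(set(ids)) != len(ids):
                raise GenotypeError(f"duplicate {name} ids")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
            raise GenotypeError(f"genotype entries must be 0/1/2/missing, found {bad!r}")

    # -- basic queries -------------------------------------------------

    @property
    def n_animals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.animal_ids.copy(), self.marker_ids.copy(), self.values.copy(),
            self.oriented_minor,
        )

    # -- subsetting ----------------------------------------------------

    def _animal_indexer(self, ids: Sequence) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            return np.asarray([lookup[a] for a in ids], dtype=int)
        except KeyError as exc:
            raise GenotypeError(f"unknown animal id {exc.args[0]!r}") from None

    def subset_animals(self, ids: Sequence) -> "GenotypeMatrix":
        """Rows for ``ids`` in the given order."""
        idx = self._animal_indexer(ids)
        return GenotypeMatrix(
            self.animal_ids[idx], self.marker_ids.copy(), self.values[idx],
            self.oriented_minor,
        )

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Columns selected by boolean mask or integer index, order preserved."""
        keep = np.asarray(keep)
        return GenotypeMatrix(
            self.animal_ids.copy(), self.marker_ids[keep], self.values[:, keep],
            self.oriented_minor,
        )

    def reorder_markers(self, marker_ids: Sequence) -> "GenotypeMatrix":
        lookup = {m: j for j, m in enumerate(self.marker_ids)}
        missing = [m for m in marker_ids if m not in lookup]
        if missing:
            raise GenotypeError(f"markers absent from matrix: {missing[:5]}")
        idx = np.asarray([lookup[m] for m in marker_ids], dtype=int)
        return self.subset_markers(idx)

    def concat_animals(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        """Stack two matrices over the same markers (order-normalized)."""
        other = other.reorder_markers(self.marker_ids)
        overlap = set(self.animal_ids) & set(other.animal_ids)
        if overlap:
            raise GenotypeError(f"animal id collision: {sorted(overlap)[:5]}")
        return GenotypeMatrix(
            np.concatenate([self.animal_ids, other.animal_ids]),
            self.marker_ids.copy(),
            np.vstack([self.values, other.values]),
            self.oriented_minor and other.oriented_minor,
        )


@dataclass
class AlleleFrequencies:
    """Per-marker counted-allele frequency over non-missing entries."""

    marker_ids: np.ndarray
    frequency: np.ndarray        # NaN for markers with no non-missing entry
    n_nonmissing: np.ndarray     # per-marker count of non-missing genotypes

    @property
    def all_missing(self) -> np.ndarray:
        """Boolean mask of markers with zero non-missing entries."""
        return self.n_nonmissing == 0

    def as_series(self) -> pd.Series:
        return pd.Series(self.frequency, index=list(self.marker_ids), name="frequency")


def compute_allele_frequencies(G: GenotypeMatrix) -> AlleleFrequencies:
    """Counted-allele frequency per marker: sum(g) / (2 × non-missing count).

    Markers with every entry missing get frequency NaN and are flagged via
    :attr:`AlleleFrequencies.all_missing` rather than silently given a value.
    """
    n_obs = (~G.missing_mask).sum(axis=0)
    total = np.nansum(G.values, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, total / (2.0 * np.maximum(n_obs, 1)), np.nan)
    return AlleleFrequencies(G.marker_ids.copy(), freq, n_obs.astype(int))


def recode_minor_allele(G: GenotypeMatrix) -> GenotypeMatrix:
    """Flip markers counting the major allele so every column counts the minor.

    A column with counted-allele frequency > 0.5 is recoded g → 2 − g
    (missing stays missing); a frequency of exactly 0.5 is left as is.
    Heterozygote counts are preserved exactly.
    """
    freqs = compute_allele_frequencies(G)
    flip = freqs.frequency > 0.5  # NaN compares False: all-missing untouched
    values = G.values.copy()
    values[:, flip] = 2.0 - values[:, flip]
    if flip.any():
        logger.debug("recode_minor_allele: flipped %d of %d markers",
                     int(flip.sum()), G.n_markers)
    return GenotypeMatrix(G.animal_ids.copy(), G.marker_ids.copy(), values, True)


def filter_maf(G: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Remove markers with minor-allele frequency strictly below ``threshold``.

    Also removes markers whose entries are all missing.  Requires a
    minor-oriented matrix.  Survivor order is preserved.
    """
    if not 0.0 <= threshold <= 0.5:
        raise GenotypeError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    if not G.oriented_minor:
        raise GenotypeError("filter_maf requires a minor-oriented matrix; "
                            "run recode_minor_allele first")
    freqs = compute_allele_frequencies(G)
    keep = (freqs.frequency >= threshold) & ~freqs.all_missing
    n_removed = int((~keep).sum())
    logger.info("filter_maf: removed %d of %d markers (threshold %.3g, "
                "%d all-missing)", n_removed, G.n_markers, threshold,
                int(freqs.all_missing.sum()))
    return G.subset_markers(keep)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def impute_missing(
    G: GenotypeMatrix, frequencies: AlleleFrequencies | None = None
) -> GenotypeMatrix:
    """Fill missing entries at marker j with ``round(2 p_j)``, half rounding up.

    ``p_j`` is the marker's minor-allele frequency, computed within ``G``
    unless external ``frequencies`` (e.g. from a reference population) are
    supplied.  Non-missing entries are untouched; the output has no missing
    entries.
    """
    if not G.oriented_minor:
        raise GenotypeError("impute_missing requires a minor-oriented matrix; "
                            "run recode_minor_allele first")
    if frequencies is None:
        frequencies = compute_allele_frequencies(G)
    else:
        if list(frequencies.marker_ids) != list(G.marker_ids):
            freq = frequencies.as_series().reindex(list(G.marker_ids))
            if freq.isna().any() and G.missing_mask[:, freq.isna().to_numpy()].any():
                raise GenotypeError("external frequencies missing for markers "
                                    "that contain missing genotypes")
            frequencies = AlleleFrequencies(
                G.marker_ids.copy(), freq.to_numpy(float),
                np.where(freq.notna(), 1, 0),
            )
    mask = G.missing_mask
    if not mask.any():
        return G.copy()
    needs = mask.any(axis=0)
    no_freq = needs & np.isnan(frequencies.frequency)
    if no_freq.any():
        bad = list(G.marker_ids[no_freq][:5])
        raise GenotypeError(
            f"markers with all entries missing and no external frequency: {bad}; "
            "filter them out first (filter_maf removes all-missing markers)"
        )
    fill = _round_half_up(2.0 * frequencies.frequency)
    values = np.where(mask, np.broadcast_to(fill, G.values.shape), G.values)
    logger.info("impute_missing: imputed %d entries", int(mask.sum()))
    return GenotypeMatrix(G.animal_ids.copy(), G.marker_ids.copy(), values, True)


@dataclass
class QCReport:
    """Counts reported by :func:`qc_pipeline`."""

    n_markers_in: int
    n_markers_out: int
    n_flipped: int
    n_removed_maf: int
    n_all_missing: int
    n_imputed: int
    missing_rate_in: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def qc_pipeline(
    G: GenotypeMatrix,
    maf_threshold: float = 0.05,
    frequencies: AlleleFrequencies | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Orient minor allele → MAF filter → impute, returning matrix and report.

    Frequencies for the filter are computed on non-missing entries before
    imputation, so imputation cannot feed back into the filter.
    """
    freqs0 = compute_allele_frequencies(G)
    n_flipped = int((freqs0.frequency > 0.5).sum())
    oriented = recode_minor_allele(G)
    filtered = filter_maf(oriented, maf_threshold)
    n_imputed = filtered.n_missing
    imputed = impute_missing(filtered, frequencies)
    report = QCReport(
        n_markers_in=G.n_markers,
        n_markers_out=imputed.n_markers,
        n_flipped=n_flipped,
        n_removed_maf=G.n_markers - filtered.n_markers
        - int(freqs0.all_missing.sum()),
        n_all_missing=int(freqs0.all_missing.sum()),
        n_imputed=n_imputed,
        missing_rate_in=G.n_missing / max(G.values.size, 1),
    )
    return imputed, report


# ----------------------------------------------------------------------
# I/O: TSV dialect and VCF
# ----------------------------------------------------------------------

_TSV_VALUES = {"0": 0.0, "1": 1.0, "2": 2.0, "NA": np.nan}


def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from the TSV dialect or a VCF.

    TSV dialect: tab-separated, header ``animal_id<TAB>m1<TAB>m2...``,
    entries ``0|1|2|NA``.  VCF: bi-allelic SNP records only; the entry is
    the ALT-allele count (0/0→0, 0/1→1, 1/1→2, ./.→missing); multi-allelic
    or non-SNP records are skipped with a logged count.  Orientation to the
    minor allele is a separate step (:func:`recode_minor_allele`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise GenotypeError(f"unknown genotype format {format!r} (expected tsv or vcf)")


def _read_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "animal_id":
        raise GenotypeError(
            f"{path}: first TSV column must be 'animal_id', got {df.columns[0]!r}"
        )
    marker_ids = np.asarray(df.columns[1:], dtype=object)
    animal_ids = df["animal_id"].to_numpy(dtype=object)
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=float)
    for (i, j), entry in np.ndenumerate(raw):
        try:
            values[i, j] = _TSV_VALUES[entry]
        except KeyError:
            raise GenotypeError(
                f"{path}: malformed entry {entry!r} at row {i + 2}, "
                f"column {marker_ids[j]!r} (expected 0/1/2/NA)"
            ) from None
    return GenotypeMatrix(animal_ids, marker_ids, values)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF  # optional dependency, VCF input only

    vcf = VCF(str(path))
    animal_ids = np.asarray(vcf.samples, dtype=object)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            n_skipped += 1
            continue
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(variant.gt_types)
        col = np.select(
            [gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan
        )
        marker_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        columns.append(col)
    vcf.close()
    if n_skipped:
        logger.warning("read_genotypes(vcf): skipped %d multi-allelic/non-SNP "
                       "records", n_skipped)
    values = (np.column_stack(columns) if columns
              else np.empty((len(animal_ids), 0)))
    return GenotypeMatrix(animal_ids, np.asarray(marker_ids, dtype=object), values)


def write_genotypes(G: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV dialect (UTF-8, Unix newlines, entries 0|1|2|NA)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("animal_id\t" + "\t".join(str(m) for m in G.marker_ids) + "\n")
        for i, animal in enumerate(G.animal_ids):
            row = G.values[i]
            cells = ["NA" if np.isnan(v) else str(int(v)) for v in row]
            fh.write(str(animal) + "\t" + "\t".join(cells) + "\n")
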