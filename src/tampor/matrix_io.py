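"""Abundance-matrix data model, file I/O and pre-correction filters.

The in-memory containers are plain :class:`pandas.DataFrame` objects:

* **abundance matrix** — features (rows) x samples (columns) of positive
  intensities in arbitrary units; missing values are ``NaN``.  Row index =
  feature identifiers, column index = sample identifiers, both unique.
* **sample annotation** — one row per sample (index = sample identifier)
  with a required ``batch`` column, an optional boolean ``is_gis`` column
  (absent means no bridging standards) and any number of free trait columns
  (diagnosis, sex, age, ...).

On disk the matrix is a TSV (or CSV) whose first column holds feature ids
and whose header row holds sample ids; missing values are written as ``NA``
and read from empty cells, ``NA``, ``NaN`` or any non-numeric token.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FilterReport",
    "read_abundance",
    "write_abundance",
    "read_annotation",
    "validate_annotation",
    "sanitize_nonpositive",
    "filter_rows_by_missingness",
    "censor_low_signal",
    "transpose_for_multiplatform",
]



@dataclass
class FilterReport:
    """Outcome of a row-level filter.

    Attributes
    ----------
    removed_feature_ids : list of str
        Features dropped, in their original order.
    missing_fraction : pandas.Series
        Per-feature fraction that drove the decision (missing, or
        noise-plus-missing for the censoring filter), indexed by feature.
    threshold : float
        The fraction threshold that was applied.
    rule : str
        Human-readable comparison rule, e.g. ``"missing >= 0.5"``.
    n_censored : int
        Cells newly set to missing (censoring filter only).
    """

    removed_feature_ids: list = field(default_factory=list)
    missing_fraction: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    threshold: float = 0.5
    rule: str = ""
    n_censored: int = 0


def _check_unique(values, what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dups = sorted(set(idx[idx.duplicated()].astype(str)))
        raise ValueError(f"duplicate {what} identifiers: {', '.join(dups)}")


def read_abundance(path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a feature x sample abundance table.

    Parameters
    ----------
    path : str or path-like
        File with feature ids in the first column and sample ids in the
        header row.
    dialect : {"tsv", "csv"}
        Field separator convention.

    Returns
    -------
    pandas.DataFrame
        Float matrix with ``NaN`` for empty/``NA``/non-numeric cells.

    Raises
    ------
    ValueError
        On duplicate feature or sample identifiers, or ragged rows
        (reported with the offending line number).
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    header = text.split("\n", 1)[0].rstrip("\r").split(sep)
    _check_unique(header[1:], "sample")
    import io as _io

    try:
        raw = pd.read_csv(
            _io.StringIO(text), sep=sep, header=0, index_col=0, dtype=str,
            keep_default_na=False, na_values=[], skip_blank_lines=False,
        )
    except pd.errors.ParserError as exc:  # pandas reports the line number
        raise ValueError(f"ragged or malformed row in {path}: {exc}") from exc
    _check_unique(raw.index, "feature")
    # any token that does not parse as a number (including NA spellings)
    # becomes missing
    mat = raw.apply(pd.to_numeric, errors="coerce")
    mat.index.name = "feature_id"
    return mat.astype(float)


def write_abundance(matrix: pd.DataFrame, path, dialect: str = "tsv") -> None:
    """Write an abundance matrix; missing values become ``NA``.

    Values round-trip losslessly through :func:`read_abundance` (pandas
    writes shortest-exact float representations).
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    out = matrix.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep=sep, na_rep="NA")


def read_annotation(path, dialect: str | None = None) -> pd.DataFrame:
    """Read a sample annotation table (columns: sample_id, batch, [is_gis], traits).

    ``is_gis`` accepts true/false/1/0 in any case; absent means all-False.
    """
    if dialect is None:
        dialect = "csv" if str(path).endswith(".csv") else "tsv"
    sep = {"tsv": "\t", "csv": ","}[dialect]
    ann = pd.read_csv(path, sep=sep)
    if "sample_id" not in ann.columns or "batch" not in ann.columns:
        raise ValueError("annotation must have 'sample_id' and 'batch' columns")
    _check_unique(ann["sample_id"], "sample")
    ann = ann.set_index("sample_id")
    ann["batch"] = ann["batch"].astype(str)
    if "is_gis" in ann.columns:
        truthy = {"true": True, "1": True, "t": True, "yes": True,
                  "false": False, "0": False, "f": False, "no": False}
        ann["is_gis"] = (
            ann["is_gis"].astype(str).str.strip().str.lower().map(truthy)
        )
        if ann["is_gis"].isna().any():
            bad = ann.index[ann["is_gis"].isna()].tolist()
            raise ValueError(f"unparseable is_gis flag for samples: {bad}")
        ann["is_gis"] = ann["is_gis"].astype(bool)
    else:
        ann["is_gis"] = False
    return ann


def validate_annotation(matrix: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Check annotation covers exactly the matrix samples; return it aligned
    to the matrix column order."""
    missing = [s for s in matrix.columns if s not in annotation.index]
    if missing:
        raise ValueError(f"samples missing from annotation: {missing}")
    ann = annotation.loc[list(matrix.columns)].copy()
    ann["batch"] = ann["batch"].astype(str)
    if "is_gis" not in ann.columns:
        ann["is_gis"] = False
    ann["is_gis"] = ann["is_gis"].astype(bool)
    return ann


def sanitize_nonpositive(matrix: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Convert zero and negative values to missing.

    Ratios are taken in log2, so non-positive intensities cannot
    participate; real instrument exports nonetheless contain zeros.

    Returns the sanitized matrix and the number of converted cells; a
    warning is logged when the count is non-zero.
    """
    bad = matrix.le(0)
    count = int(bad.to_numpy().sum())
    if count:
        logger.warning("sanitize_nonpositive: %d non-positive values set to missing", count)
        matrix = matrix.mask(bad)
    return matrix, count


def filter_rows_by_missingness(
    matrix: pd.DataFrame, max_missing_frac: float = 0.5
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop features missing in at least ``max_missing_frac`` of samples.

    The comparison is ``>=``: a feature missing in exactly half of the
    samples is removed at the default threshold. Survivor order is
    preserved.
    """
    if not 0 < max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in (0, 1]")
    frac = matrix.isna().mean(axis=1)
    keep = frac < max_missing_frac
    if not keep.any():
        raise ValueError(
            "all features removed by the missingness filter; "
            f"review the threshold ({max_missing_frac})"
        )
    report = FilterReport(
        removed_feature_ids=matrix.index[~keep].tolist(),
        missing_fraction=frac,
        threshold=max_missing_frac,
        rule=f"missing >= {max_missing_frac}",
    )
    return matrix.loc[keep], report


def censor_low_signal(
    matrix: pd.DataFrame, noise_threshold: float, max_noise_frac: float
) -> tuple[pd.DataFrame, FilterReport]:
    """Left-tail censoring for count-type (e.g. transcriptomic) input.

    Values at or below ``noise_threshold`` become missing; features whose
    combined noise-plus-missing fraction then *exceeds* ``max_noise_frac``
    are removed.
    """
    if noise_threshold < 0:
        raise ValueError("noise_threshold must be >= 0")
    censored = matrix.mask(matrix.le(noise_threshold))
    n_censored = int(matrix.notna().to_numpy().sum() - censored.notna().to_numpy().sum())
    frac = censored.isna().mean(axis=1)
    keep = frac <= max_noise_frac
    if not keep.any():
        raise ValueError(
            "all features removed by low-signal censoring; "
            f"review thresholds (noise <= {noise_threshold}, frac > {max_noise_frac})"
        )
    report = FilterReport(
        removed_feature_ids=matrix.index[~keep].tolist(),
        missing_fraction=frac,
        threshold=max_noise_frac,
        rule=f"noise+missing > {max_noise_frac}",
        n_censored=n_censored,
    )
    return censored.loc[keep], report


def _accession(feature_id: str) -> str:
    return feature_id.split("@", 1)[0]


def transpose_for_multiplatform(
    matrix: pd.DataFrame,
    platform_of_feature: pd.Series | dict,
    common_feature_ids,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recast a multi-platform matrix so platforms become batches.

    The combined matrix holds assays from several measurement platforms as
    rows. Transposition puts original samples on rows and assays on
    columns; each column is annotated with its platform as the batch label
    and flagged as a bridging (GIS) column when its accession belongs to
    ``common_feature_ids`` — the accessions measured on every platform.

    Row identifiers may be plain accessions or ``accession@platform``;
    output column identifiers are always made unique as
    ``accession@platform``.

    Requires complete data (multi-platform harmonization is defined on
    assays without missing values) and at least two platforms; every common
    accession must occur exactly once per platform.
    """
    pmap = pd.Series(platform_of_feature, dtype=str)
    unlabeled = [f for f in matrix.index if f not in pmap.index]
    if unlabeled:
        raise ValueError(f"features without platform label: {unlabeled[:5]}")
    pmap = pmap.loc[list(matrix.index)]
    platforms = sorted(pmap.unique())
    if len(platforms) < 2:
        raise ValueError("multi-platform harmonization needs >= 2 platforms")
    if matrix.isna().to_numpy().any():
        raise ValueError(
            "missing values present: impute or drop incomplete assays before "
            "transposed harmonization"
        )
    common = list(common_feature_ids)
    acc = matrix.index.map(_accession)
    for c in common:
        for p in platforms:
            n = int(((acc == c) & (pmap.to_numpy() == p)).sum())
            if n == 0:
                raise ValueError(f"common feature {c!r} absent from platform {p!r}")
            if n > 1:
                raise ValueError(f"common feature {c!r} duplicated on platform {p!r}")
    new_ids = [f"{_accession(f)}@{pmap[f]}" for f in matrix.index]
    _check_unique(new_ids, "assay")
    transposed = matrix.T.copy()
    transposed.columns = new_ids
    transposed.index.name = "feature_id"
    annotation = pd.DataFrame(
        {
            "batch": pmap.to_numpy(),
            "is_gis": [a in set(common) for a in acc],
        },
        index=pd.Index(new_ids, name="sample_id"),
    )
    return transposed, annotation
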