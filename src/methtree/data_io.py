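"""Reading, writing and preprocessing of methylation beta matrices.

The on-disk convention follows Xena-style downloads: CpG probes as rows,
samples as columns, first column the probe identifier, header row the
sample identifiers.  Beta values are fractions in [0, 1); missing cells
are encoded as ``NA`` or left empty.  The companion sample manifest and
probe annotation are plain TSV tables.

In memory a beta matrix is a :class:`pandas.DataFrame` indexed by probe id
with sample-id columns; the manifest and annotation are DataFrames with
the documented required columns.
"""

from __future__ import annotations

import logging
import math
import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("methtree")

MANIFEST_COLUMNS = ("sample_id", "cancer_type", "subtype", "cohort")
ANNOTATION_COLUMNS = ("probe_id", "chromosome")

#: chromosome names treated as sex chromosomes (case-insensitive)
SEX_CHROMOSOMES = frozenset({"x", "y", "chrx", "chry", "23", "24"})

_PROBE_ID_RE = re.compile(r"^(cg|ch\.|rs)\d")


class EmptyPanelError(ValueError):
    """Raised when a filtering step leaves no probes at all."""


# ---------------------------------------------------------------------------
# beta values
# ---------------------------------------------------------------------------

def compute_beta(methylated, unmethylated):
    """Beta value from methylated/unmethylated intensities: M / (M + U + 100).

    The pseudo-count of 100 in the denominator stabilises low-intensity
    probes and keeps the result strictly below 1.  Accepts scalars or
    arrays (broadcast together).

    Raises
    ------
    ValueError
        If any intensity is negative.
    """
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if np.any(m < 0) or np.any(u < 0):
        raise ValueError("intensities must be non-negative")
    beta = m / (m + u + 100.0)
    if np.ndim(methylated) == 0 and np.ndim(unmethylated) == 0:
        return float(beta)
    return beta


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: str) -> str:
    p = str(path)
    for gz in (".gz",):
        if p.endswith(gz):
            p = p[: -len(gz)]
    return "," if p.endswith(".csv") else "\t"


def _looks_like_probe_ids(values: Iterable[str]) -> float:
    vals = [str(v) for v in values]
    if not vals:
        return 0.0
    hits = sum(1 for v in vals if _PROBE_ID_RE.match(v))
    return hits / len(vals)


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a probes x samples beta matrix from TSV/CSV (gzip transparent).

    Auto-detects a transposed (samples x probes) file by testing whether
    the row index or the header looks like 450K probe ids and transposes
    back so the result is always probes x samples.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, na_values=["NA", ""])
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    row_score = _looks_like_probe_ids(df.index[: min(len(df.index), 50)])
    col_score = _looks_like_probe_ids(df.columns[: min(len(df.columns), 50)])
    if col_score > row_score:
        logger.warning("matrix at %s looks transposed; transposing to probes x samples", path)
        df = df.T
    df = df.astype(float)
    validate_beta_matrix(df)
    return df


def write_beta_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep=_sep_for(path), index_label="probe_id", na_rep="NA")


def validate_beta_matrix(matrix: pd.DataFrame) -> None:
    """Check the beta-matrix invariants: unique ids, values in [0, 1)."""
    if matrix.index.duplicated().any():
        raise ValueError("duplicate probe ids in beta matrix")
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate sample ids in beta matrix")
    vals = matrix.to_numpy(dtype=float)
    finite = np.isfinite(vals)
    if finite.any():
        observed = vals[finite]
        if observed.min() < 0 or observed.max() >= 1:
            raise ValueError("beta values must lie in [0, 1)")


def read_manifest(path) -> pd.DataFrame:
    """Read a sample manifest TSV.

    Required columns: sample_id, cancer_type, subtype, cohort.  A ``split``
    column ({train, test, unassigned}) is added as ``unassigned`` if absent.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in manifest")
    if "split" not in df.columns:
        df["split"] = "unassigned"
    return df.reset_index(drop=True)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep=_sep_for(path), index=False)


def read_annotation(path) -> pd.DataFrame:
    """Read a probe annotation TSV with columns probe_id, chromosome."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation missing required columns: {missing}")
    if df["probe_id"].duplicated().any():
        raise ValueError("duplicate probe ids in annotation")
    return df.reset_index(drop=True)


def check_manifest_matches_matrix(matrix: pd.DataFrame, manifest: pd.DataFrame) -> None:
    """Every manifest sample must have a matrix column and vice versa."""
    mat = set(matrix.columns)
    man = set(manifest["sample_id"])
    if mat != man:
        only_mat = sorted(mat - man)[:5]
        only_man = sorted(man - mat)[:5]
        raise ValueError(
            f"manifest/matrix sample mismatch (matrix-only e.g. {only_mat}, "
            f"manifest-only e.g. {only_man})"
        )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_probes(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    cohort_probe_sets: Sequence[Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Apply the probe filters used before any modelling.

    Retains, in the input row order, probes that are (a) shared across all
    ``cohort_probe_sets`` (when given), (b) not on a sex chromosome per the
    annotation, and (c) free of missing values.  Probes absent from the
    annotation are treated as autosomal and kept, with a warning.

    Raises
    ------
    EmptyPanelError
        If no probe survives.
    """
    keep = pd.Series(True, index=matrix.index)
    if cohort_probe_sets:
        shared = None
        for s in cohort_probe_sets:
            s = set(s)
            shared = s if shared is None else shared & s
        keep &= matrix.index.isin(shared)
    if annotation is not None:
        chrom = annotation.set_index("probe_id")["chromosome"].astype(str)
        chrom = chrom.reindex(matrix.index)
        unannotated = chrom.isna()
        if unannotated.any():
            logger.warning(
                "%d probes absent from the annotation; treated as autosomal",
                int(unannotated.sum()),
            )
        is_sex = chrom.str.lower().isin(SEX_CHROMOSOMES).fillna(False)
        keep &= ~is_sex
    keep &= matrix.notna().all(axis=1) & np.isfinite(matrix).all(axis=1)
    out = matrix.loc[keep]
    if out.shape[0] == 0:
        raise EmptyPanelError("no probes survive filtering")
    return out


def filter_subtypes(manifest: pd.DataFrame, min_samples: int = 5,
                    min_fraction: float = 0.10,
                    exclude_subtypes: Iterable[str] = ()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop under-represented clinical subtypes.

    A subtype is removed when it has fewer than ``min_samples`` samples or
    contributes less than ``min_fraction`` of its cancer type's samples.
    Subtypes listed in ``exclude_subtypes`` (e.g. ambiguous annotations)
    are removed unconditionally.

    Returns the filtered manifest and a table of removed subtypes with the
    reason for each removal.  A cancer type losing all of its subtypes is
    dropped with a warning.
    """
    exclude = set(exclude_subtypes)
    removed = []
    keep_mask = pd.Series(True, index=manifest.index)
    for (ctype, subtype), grp in manifest.groupby(["cancer_type", "subtype"], sort=True):
        n = len(grp)
        type_total = int((manifest["cancer_type"] == ctype).sum())
        reason = None
        if subtype in exclude:
            reason = "excluded"
        elif n < min_samples:
            reason = f"count {n} < {min_samples}"
        elif n / type_total < min_fraction:
            reason = f"fraction {n / type_total:.3f} < {min_fraction}"
        if reason is not None:
            keep_mask[grp.index] = False
            removed.append({"cancer_type": ctype, "subtype": subtype,
                            "n_samples": n, "reason": reason})
    out = manifest.loc[keep_mask].reset_index(drop=True)
    for ctype in sorted(set(manifest["cancer_type"]) - set(out["cancer_type"])):
        logger.warning("cancer type %s lost all subtypes and was dropped", ctype)
    return out, pd.DataFrame(removed, columns=["cancer_type", "subtype", "n_samples", "reason"])


def stratified_split(manifest: pd.DataFrame, ratio: float = 0.8,
                     seed: int = 0) -> pd.DataFrame:
    """Assign train/test splits stratified by cancer type.

    Per type, floor(ratio * n) samples go to training and the remainder to
    test, which guarantees at least one test sample whenever n >= 2.  The
    assignment is a deterministic function of ``seed``.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = manifest.copy()
    out["split"] = "unassigned"
    for ctype, grp in out.groupby("cancer_type", sort=True):
        n = len(grp)
        if n < 2:
            raise ValueError(f"cancer type {ctype!r} has only {n} sample(s); cannot split")
        order = grp.sort_values("sample_id").index.to_numpy()
        perm = rng.permutation(len(order))
        n_train = math.floor(ratio * n)
        train_idx = order[perm[:n_train]]
        test_idx = order[perm[n_train:]]
        out.loc[train_idx, "split"] = "train"
        out.loc[test_idx, "split"] = "test"
    return out
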