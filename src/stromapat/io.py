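"""Matrix and clinical-table ingestion, validation and writing.

All in-memory matrices are pandas DataFrames: expression is gene-by-sample
(nonnegative, log-scale), methylation is locus-by-sample (beta values in
[0, 1]).  Feature-id matching across matrices is exact-string everywhere —
no gene-symbol aliasing is ever applied.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

logger = logging.getLogger("stromapat")

FLOAT_FORMAT = "%.10g"  # deterministic text round-trips


class DataError(ValueError):
    """Input data violates a structural contract (range, ids, missingness)."""


def _check_unique(ids, what: str, path=None) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique().tolist()[:5]
        where = f" in {path}" if path else ""
        raise DataError(f"duplicate {what} ids{where}: {dup}")


def validate_expression(df: pd.DataFrame, *, impute_zero: bool = False,
                        log2p1: bool = False) -> pd.DataFrame:
    """Validate a gene-by-sample expression matrix.

    Parameters
    ----------
    impute_zero:
        Replace missing entries with 0 (intended for sparse single-cell
        input where absence means undetected).
    log2p1:
        Apply ``log2(x + 1)`` — use when the input is raw counts rather
        than log-scale intensities.
    """
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    if df.isna().any().any():
        if impute_zero:
            df = df.fillna(0.0)
        else:
            gene = df.index[df.isna().any(axis=1)][0]
            raise DataError(f"missing expression values (first at gene {gene!r}); "
                            "pass impute_zero=True for sparse input")
    df = df.astype(float)
    if (df.to_numpy() < 0).any():
        gene = df.index[(df < 0).any(axis=1)][0]
        raise DataError(f"negative expression at gene {gene!r}")
    if log2p1:
        df = np.log2(df + 1.0)
    return df


def validate_methylation(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a locus-by-sample beta matrix (all entries in [0, 1])."""
    _check_unique(df.index, "locus")
    _check_unique(df.columns, "sample")
    if df.isna().any().any():
        locus = df.index[df.isna().any(axis=1)][0]
        raise DataError(f"missing beta value at locus {locus!r}")
    df = df.astype(float)
    bad = (df < 0) | (df > 1)
    if bad.any().any():
        locus = df.index[bad.any(axis=1)][0]
        col = df.columns[bad.loc[locus].to_numpy().nonzero()[0][0]]
        raise DataError(f"beta value outside [0, 1] at locus {locus!r}, sample {col!r}")
    return df


def read_matrix(path, kind: str = "expression", *, impute_zero: bool = False,
                log2p1: bool = False) -> pd.DataFrame:
    """Read a feature-by-sample matrix from dense TSV/CSV or MTX triplet.

    MTX input (``X.mtx``) expects sidecar id files ``X.rows.txt`` (feature
    ids) and ``X.cols.txt`` (sample ids), one id per line.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        m = scipy.io.mmread(path)
        if scipy.sparse.issparse(m):
            m = m.toarray()
        rows = (path.parent / (path.stem + ".rows.txt")).read_text().split()
        cols = (path.parent / (path.stem + ".cols.txt")).read_text().split()
        if m.shape != (len(rows), len(cols)):
            raise DataError(f"{path}: matrix shape {m.shape} does not match "
                            f"sidecar ids ({len(rows)} rows, {len(cols)} cols)")
        df = pd.DataFrame(m, index=rows, columns=cols)
    else:
        sep = "," if path.suffix == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        if kind == "methylation":
            return validate_methylation(df)
        return validate_expression(df, impute_zero=impute_zero, log2p1=log2p1)
    except DataError as err:
        raise DataError(f"{path}: {err}") from None


def write_matrix(df: pd.DataFrame, path) -> Path:
    """Write a matrix as TSV (or MTX triplet when *path* ends in .mtx)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(df.to_numpy()))
        (path.parent / (path.stem + ".rows.txt")).write_text(
            "\n".join(map(str, df.index)) + "\n")
        (path.parent / (path.stem + ".cols.txt")).write_text(
            "\n".join(map(str, df.columns)) + "\n")
    else:
        sep = "," if path.suffix == ".csv" else "\t"
        df.to_csv(path, sep=sep, float_format=FLOAT_FORMAT)
    return path


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV with required columns sample_id, time_days, event."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "time_days", "event"):
        if col not in df.columns:
            raise DataError(f"{path}: clinical table lacks required column {col!r}")
    _check_unique(df["sample_id"], "sample", path)
    df = df.set_index("sample_id")
    if (df["time_days"] <= 0).any() or df["time_days"].isna().any():
        raise DataError(f"{path}: time_days must be positive and non-missing")
    if not df["event"].isin([0, 1]).all():
        raise DataError(f"{path}: event must be 0/1")
    return df


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

_CONFIG_SCHEMA: dict[str, tuple[type, object, object]] = {
    # name: (type, low, high); bounds None = unchecked
    "seed": (int, 0, 2**31 - 1),
    "out_dir": (str, None, None),
    "n_genes": (int, 10, None),
    "n_samples": (int, 4, None),
    "k_true": (int, 2, None),
    "markers_per_pattern": (int, 1, None),
    "background_level": (float, 0.0, None),
    "noise_sd": (float, 0.0, None),
    "k_min": (int, 2, None),
    "k_max": (int, 3, None),
    "n_runs": (int, 2, None),
    "max_iter": (int, 1, None),
    "tol": (float, 0.0, None),
    "drop_tol": (float, 0.0, None),
    "sigma_mult": (float, 0.0, None),
    "alpha": (float, 0.0, 1.0),
    "n_loci_panel": (int, 10, None),
    "n_informative": (int, 2, None),
    "n_loci_select": (int, 2, None),
    "cell_types": (list, None, None),
    "profiles_per_type": (int, 2, None),
    "delta": (float, 0.0, 1.0),
    "beta_noise_sd": (float, 0.0, None),
    "dirichlet_alpha": (list, None, None),
    "n_bulk_samples": (int, 5, None),
    "n_cells_per_type": (int, 2, None),
    "dropout_rate": (float, 0.0, 1.0),
    "log_hr": (float, None, None),
    "baseline_rate": (float, 0.0, None),
    "censor_rate": (float, 0.0, None),
    "cut": (str, None, None),
    "minprop": (float, 0.0, 0.5),
    "stages": (list, None, None),
}

_DEFAULT_CONFIG: dict = {
    "seed": 1,
    "out_dir": "pipeline_out",
    # planted-pattern expression
    "n_genes": 900,
    "n_samples": 60,
    "k_true": 6,
    "markers_per_pattern": 30,
    "background_level": 0.05,
    "noise_sd": 0.1,          # multiple of the noiseless signal sd
    # NMF / rank scan
    "k_min": 2,
    "k_max": 9,
    "n_runs": 30,
    "max_iter": 500,
    "tol": 1e-6,
    "drop_tol": 0.01,
    # markers & projection
    "sigma_mult": 3.0,
    "alpha": 0.05,
    # methylation panel & deconvolution
    "n_loci_panel": 2000,
    "n_informative": 200,
    "n_loci_select": 400,
    "cell_types": ["cancer", "stromal", "immune"],
    "profiles_per_type": 20,
    "delta": 0.5,
    "beta_noise_sd": 0.03,
    "dirichlet_alpha": [2.0, 2.0, 2.0],
    "n_bulk_samples": 100,
    # single cells
    "n_cells_per_type": 100,
    "dropout_rate": 0.3,
    # survival
    "log_hr": 0.6931471805599453,   # log 2
    "baseline_rate": 0.002,
    "censor_rate": 0.001,
    "cut": "optimal",
    "minprop": 0.1,
    "stages": ["simulate", "nmf", "markers", "project",
               "deconvolve", "ctexpr", "survival"],
}


class PipelineConfig(dict):
    """Validated pipeline configuration: typed keys, range checks, no extras."""

    def __init__(self, **overrides):
        cfg = dict(_DEFAULT_CONFIG)
        unknown = set(overrides) - set(_CONFIG_SCHEMA)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(overrides)
        for key, (typ, low, high) in _CONFIG_SCHEMA.items():
            val = cfg[key]
            if typ is float and isinstance(val, int):
                val = cfg[key] = float(val)
            if not isinstance(val, typ):
                raise ValueError(f"config key {key!r}: expected {typ.__name__}, "
                                 f"got {type(val).__name__}")
            if low is not None and typ in (int, float) and val < low:
                raise ValueError(f"config key {key!r}: {val} below minimum {low}")
            if high is not None and typ in (int, float) and val > high:
                raise ValueError(f"config key {key!r}: {val} above maximum {high}")
        if len(cfg["dirichlet_alpha"]) != len(cfg["cell_types"]):
            raise ValueError("dirichlet_alpha length must match cell_types")
        super().__init__(cfg)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls(**raw)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path
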