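"""Readers and writers for the tool's tabular formats.

All tables are UTF-8 TSV with a header row, '.' decimal separator and '-'
for missing values.  The genotype-probability reader understands the
whitespace-delimited IMPUTE/SNPTEST ``.gen`` dialect: five metadata tokens
per variant (snp id, rs id, position, alleleA, alleleB) followed by one
probability triplet (AA, AB, BB) per individual.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import CNVGenotype, SignalData, cnv_from_probabilities

__all__ = [
    "read_signal",
    "read_phenotype",
    "read_probability_matrix",
    "write_probability_matrix",
    "read_genotype_probs",
    "join_phenotype",
    "write_results",
]

_NA = "-"


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[_NA], dtype={"id": str})
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate column names")
    return df


def _require(df, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_signal(path) -> SignalData:
    """Read a signal table: columns ``id``, ``intensity``, optional ``batch``."""
    df = _read_tsv(path)
    _require(df, ["id", "intensity"], path)
    if df["id"].duplicated().any():
        raise ValueError(f"{path}: duplicate ids")
    if df["intensity"].isna().any():
        n = int(df["intensity"].isna().sum())
        warnings.warn(f"{path}: dropping {n} rows with missing intensity")
        df = df.dropna(subset=["intensity"])
    batch = df["batch"].to_numpy() if "batch" in df.columns else None
    return SignalData(
        intensity=df["intensity"].to_numpy(dtype=float),
        ids=df["id"].to_numpy(),
        batch=batch,
    )


def read_phenotype(path) -> pd.DataFrame:
    """Read a phenotype table; must contain an ``id`` column."""
    df = _read_tsv(path)
    _require(df, ["id"], path)
    if df["id"].duplicated().any():
        raise ValueError(f"{path}: duplicate ids")
    return df


def read_probability_matrix(path) -> CNVGenotype:
    """Read a TSV posterior matrix: ``id`` plus one column per copy class.

    Column headers carry the copy labels (e.g. ``0``, ``1``, ``2`` or
    ``p0``, ``p1``, ``p2``); rows are renormalised to sum to 1.
    """
    df = _read_tsv(path)
    _require(df, ["id"], path)
    prob_cols = [c for c in df.columns if c != "id"]
    if not prob_cols:
        raise ValueError(f"{path}: no probability columns")
    copies = []
    for c in prob_cols:
        digits = "".join(ch for ch in str(c) if ch.isdigit() or ch == "-")
        if not digits:
            raise ValueError(f"{path}: cannot read a copy label from column {c!r}")
        copies.append(int(digits))
    prob = df[prob_cols].to_numpy(dtype=float)
    return cnv_from_probabilities(prob, copies=copies, ids=df["id"].to_numpy())


def write_probability_matrix(cnv: CNVGenotype, path) -> None:
    df = pd.DataFrame(cnv.prob, columns=[str(int(c)) for c in cnv.copies])
    df.insert(0, "id", cnv.ids)
    df.to_csv(path, sep="\t", index=False, na_rep=_NA, float_format="%.12g")


def read_genotype_probs(path, meta_cols: int = 5):
    """Parse an IMPUTE-style ``.gen`` genotype-probability file.

    Returns one ``(metadata, CNVGenotype)`` pair per variant line, with
    copy labels (0, 1, 2) for the AA/AB/BB genotype classes.  Probability
    triplets are renormalised; a triplet summing to 0 (missing data) is
    replaced by the uniform distribution with a warning.
    """
    meta_names = ["snp_id", "rs_id", "position", "alleleA", "alleleB"]
    variants = []
    n_ind = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if (len(tokens) - meta_cols) % 3 != 0 or len(tokens) <= meta_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {meta_cols} metadata tokens plus "
                    f"probability triplets, got {len(tokens)} tokens"
                )
            k = (len(tokens) - meta_cols) // 3
            if n_ind is None:
                n_ind = k
            elif k != n_ind:
                raise ValueError(
                    f"{path}:{lineno}: ragged line ({k} individuals, expected {n_ind})"
                )
            meta_vals = tokens[:meta_cols]
            names = meta_names if meta_cols == 5 else [f"meta{j}" for j in range(meta_cols)]
            meta = dict(zip(names, meta_vals))
            prob = np.array(tokens[meta_cols:], dtype=float).reshape(n_ind, 3)
            if np.any(prob < 0):
                raise ValueError(f"{path}:{lineno}: negative genotype probability")
            zero_rows = prob.sum(axis=1) <= 0
            if zero_rows.any():
                warnings.warn(
                    f"{path}:{lineno}: {int(zero_rows.sum())} missing-data triplets "
                    "set to the uniform distribution"
                )
                prob[zero_rows] = 1.0 / 3.0
            variants.append((meta, cnv_from_probabilities(prob, copies=(0, 1, 2))))
    return variants


def join_phenotype(cnv: CNVGenotype, pheno: pd.DataFrame, mode: str = "strict"):
    """Row-align a posterior matrix and a phenotype table by id.

    mode="strict" errors on any id mismatch; mode="intersect" keeps the
    common ids (in the cnv's order) and logs the drop count.
    Returns ``(cnv_aligned, pheno_aligned)``.
    """
    if mode not in ("strict", "intersect"):
        raise ValueError("mode must be 'strict' or 'intersect'")
    cnv_ids = pd.Index(np.asarray(cnv.ids).astype(str))
    ph = pheno.copy()
    ph["id"] = ph["id"].astype(str)
    ph = ph.set_index("id")
    common = cnv_ids.intersection(ph.index)
    if mode == "strict":
        if len(common) != len(cnv_ids) or len(common) != len(ph.index):
            only_cnv = cnv_ids.difference(ph.index)
            only_ph = ph.index.difference(cnv_ids)
            raise ValueError(
                "id mismatch between probability matrix and phenotype table "
                f"({len(only_cnv)} only in cnv, {len(only_ph)} only in phenotype)"
            )
        keep = np.arange(len(cnv_ids))
    else:
        dropped = len(cnv_ids) - len(common)
        if dropped or len(ph.index) != len(common):
            warnings.warn(
                f"intersect join: dropped {dropped} cnv rows and "
                f"{len(ph.index) - len(common)} phenotype rows"
            )
        keep = np.flatnonzero(cnv_ids.isin(common))
    aligned_cnv = CNVGenotype(
        prob=cnv.prob[keep],
        copies=cnv.copies,
        ids=np.asarray(cnv.ids)[keep],
        source=cnv.source,
        fit=cnv.fit,
    )
    aligned_ph = ph.loc[cnv_ids[keep]]
    aligned_ph.index.name = "id"
    return aligned_cnv, aligned_ph.reset_index()


def write_results(out_prefix, table: pd.DataFrame | None = None, sidecar: dict | None = None):
    """Write a results table (TSV) and a JSON provenance sidecar.

    The sidecar records the configuration, seeds and package version so a
    run can be reproduced from it alone.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    if table is not None:
        paths["table"] = str(out_prefix.with_suffix(".tsv"))
        table.to_csv(paths["table"], sep="\t", na_rep=_NA, float_format="%.12g")
    if sidecar is not None:
        from . import __version__

        sidecar = {"package": "cnvlatent", "version": __version__, **sidecar}
        paths["sidecar"] = str(out_prefix.with_suffix(".json"))
        with open(paths["sidecar"], "w") as fh:
            json.dump(sidecar, fh, indent=2, default=_json_default)
    return paths


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialise {type(obj).__name__}")
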