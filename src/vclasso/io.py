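"""Readers and writers for OTU tables, trees, kernels, and phenotypes.

Conventions: OTU tables are TSV/CSV with a header row of OTU ids and the
first column holding sample ids; taxonomy files map ``otu_id`` to a
cluster label (e.g. genus); trees are newick with branch lengths;
kernels are written one square TSV per cluster plus a JSON manifest with
construction diagnostics. Sample order is always taken from the
phenotype file's row order — kernels are aligned to it by id, never by
position. Readers reject malformed input rather than coercing it.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .kernels import KernelMatrix, OTUTable

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "read_tree",
    "write_tree",
    "read_phenotypes",
    "write_kernels",
    "read_kernels",
    "write_manifest",
]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_otu_table(path, taxonomy: dict[str, str] | None = None) -> OTUTable:
    """Read a sample-by-OTU count table (TSV, or CSV by extension)."""
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    for col in header:  # pandas silently mangles duplicate columns
        if col in seen:
            raise ValueError(f"{path}: duplicate OTU id {col!r}")
        seen.add(col)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty OTU table")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[df.dtypes.map(lambda d: not np.issubdtype(d, np.number))][0]
        raise ValueError(f"{path}: non-numeric entries in column {bad!r}")
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"{path}: negative count at sample {df.index[i]!r}, OTU {df.columns[j]!r}"
        )
    frac = np.argwhere(values != np.round(values))
    if frac.size:
        i, j = frac[0]
        raise ValueError(
            f"{path}: non-integer count at sample {df.index[i]!r}, "
            f"OTU {df.columns[j]!r}"
        )
    return OTUTable(
        counts=values.astype(np.int64),
        sample_ids=[str(s) for s in df.index],
        otu_ids=[str(o) for o in df.columns],
        taxon_of=taxonomy,
    )


def write_otu_table(table: OTUTable, path) -> None:
    path = Path(path)
    df = pd.DataFrame(table.counts, index=table.sample_ids, columns=table.otu_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path))


def read_taxonomy(path, level: str = "genus") -> dict[str, str]:
    """Read an OTU taxonomy table; returns otu_id -> label at ``level``.

    Expects a header with ``otu_id`` plus one column per level (e.g.
    ``genus``, ``phylum``). Empty labels map to the catch-all downstream.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    cols = {c.lower(): c for c in df.columns}
    if "otu_id" not in cols:
        raise ValueError(f"{path}: taxonomy file needs an 'otu_id' column")
    if level.lower() not in cols:
        raise ValueError(f"{path}: no {level!r} column in taxonomy file")
    otus = df[cols["otu_id"]].astype(str)
    if otus.duplicated().any():
        raise ValueError(f"{path}: duplicate otu_id in taxonomy file")
    labels = df[cols[level.lower()]]
    return {
        o: (str(l) if pd.notna(l) and str(l).strip() else "")
        for o, l in zip(otus, labels)
    }


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree; missing branch lengths become 0."""
    tree = TreeNode.read(str(path), format="newick")
    n_missing = 0
    for node in tree.postorder(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
    if n_missing:
        warnings.warn(
            f"{path}: {n_missing} branch length(s) missing, set to 0", stacklevel=2
        )
    seen = set()
    for tip in tree.tips():
        if tip.name in seen:
            raise ValueError(f"{path}: duplicate leaf label {tip.name!r}")
        seen.add(tip.name)
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_phenotypes(
    path, longitudinal: bool = False, response: str = "y"
):
    """Read a phenotype/covariate table.

    Expects columns ``subject_id``, the response (default ``y``), a
    ``visit`` column when ``longitudinal``, an optional ``sample_id``
    column, and any number of covariates. Missing covariate values are
    mean-imputed (the response never is); categorical covariates are
    one-hot encoded with the first level dropped; an intercept column is
    prepended.

    Returns ``(y, X, subject_of, sample_ids, column_names)``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    df.columns = [str(c) for c in df.columns]
    required = {"subject_id", response}
    if longitudinal:
        required.add("visit")
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing column(s) {sorted(missing_cols)}")
    if df[response].isna().any():
        row = int(df.index[df[response].isna()][0])
        raise ValueError(f"{path}: missing response value at row {row}")
    y = df[response].astype(float).to_numpy()
    subject_of = df["subject_id"].astype(str).to_numpy()
    if "sample_id" in df.columns:
        sample_ids = df["sample_id"].astype(str).tolist()
    else:
        sample_ids = [f"{s}.v{v}" for s, v in zip(subject_of, df.get("visit", range(len(df))))] \
            if longitudinal else list(subject_of)

    drop = {"subject_id", "sample_id", "visit", response}
    covars = df[[c for c in df.columns if c not in drop]]
    blocks = [pd.Series(np.ones(len(df)), name="intercept")]
    for col in covars.columns:
        s = covars[col]
        if pd.api.types.is_numeric_dtype(s):
            if s.isna().all():
                raise ValueError(f"{path}: covariate {col!r} is entirely missing")
            blocks.append(s.fillna(s.mean()).astype(float))
        else:
            if s.isna().all():
                raise ValueError(f"{path}: covariate {col!r} is entirely missing")
            dummies = pd.get_dummies(s.astype(str), prefix=col, drop_first=True)
            blocks.append(dummies.astype(float))
    X = pd.concat(blocks, axis=1)
    return y, X.to_numpy(), subject_of, sample_ids, list(X.columns)


def write_kernels(kernels: dict[str, KernelMatrix], outdir, manifest_extra=None) -> None:
    """Write one TSV per cluster kernel plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = {}
    for label, K in kernels.items():
        fname = f"kernel_{label}.tsv"
        ids = K.sample_ids or [f"S{i + 1}" for i in range(K.values.shape[0])]
        df = pd.DataFrame(K.values, index=ids, columns=ids)
        df.index.name = "sample_id"
        df.to_csv(outdir / fname, sep="\t", float_format="%.17g")
        entries[label] = {
            "file": fname,
            "frobenius_normalized": bool(K.frobenius_normalized),
            "n_clipped_eigenvalues": int(K.n_clipped),
            "clipped_magnitude": float(K.clipped_magnitude),
            "frobenius_scale_factor": float(K.scale_factor),
        }
    manifest = {"kernels": entries}
    if manifest_extra:
        manifest.update(manifest_extra)
    (outdir / "kernels_manifest.json").write_text(json.dumps(manifest, indent=2))


def read_kernels(indir, sample_ids: list[str] | None = None) -> dict[str, KernelMatrix]:
    """Read kernels written by :func:`write_kernels`.

    With ``sample_ids`` given, each kernel is re-ordered to that sample
    order (by id); missing samples raise.
    """
    indir = Path(indir)
    manifest = json.loads((indir / "kernels_manifest.json").read_text())
    out: dict[str, KernelMatrix] = {}
    for label, entry in manifest["kernels"].items():
        df = pd.read_csv(indir / entry["file"], sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if sample_ids is not None:
            missing = [s for s in sample_ids if s not in df.index]
            if missing:
                raise ValueError(
                    f"kernel {label!r} lacks sample(s) {missing[:5]}"
                )
            df = df.loc[sample_ids, sample_ids]
        out[label] = KernelMatrix(
            values=df.to_numpy(),
            cluster_label=label,
            frobenius_normalized=entry["frobenius_normalized"],
            n_clipped=entry["n_clipped_eigenvalues"],
            clipped_magnitude=entry["clipped_magnitude"],
            scale_factor=entry["frobenius_scale_factor"],
            sample_ids=list(df.index),
        )
    return out


def write_manifest(path, config: dict) -> None:
    """Write a run manifest (config, seed, software version)."""
    from . import __version__

    payload = {"version": __version__, **config}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
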