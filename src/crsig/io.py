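"""Readers and writers for the pipeline's plain-text formats.

Formats: GMT for gene sets, TSV for matrices and result tables (missing
cells written as "NA"), JSON for truth objects, manifests, and concordance
results. All writes are atomic: content goes to a temporary file in the
destination directory which is then renamed over the target, so a crashed
run never leaves truncated primary outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import FormatError
from .gsets import GeneSetCollection
from .page import ZScoreMatrix
from .probes import DifferentialResult, ExpressionStudy, ProbeTable
from .simulate import SyntheticTruth

log = logging.getLogger("crsig")


@contextmanager
def atomic_write(path: str | Path, mode: str = "w") -> Iterator:
    """Write to a sibling temp file, then rename onto ``path``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------- gene sets

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: term_id <tab> description <tab> member genes...

    Duplicate members within a line are deduplicated with a warning;
    duplicate term IDs are an error; a line with fewer than three fields
    is malformed.
    """
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs term, description, >=1 member")
            term, desc, members = fields[0], fields[1], [f for f in fields[2:] if f]
            if not members:
                raise FormatError(f"{path}:{lineno}: term {term!r} has no members")
            if term in sets:
                raise FormatError(f"{path}:{lineno}: duplicate term ID {term!r}")
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                log.warning("%s:%d: term %s has duplicate members; deduplicated", path, lineno, term)
            sets[term] = frozenset(unique)
            names[term] = desc
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return GeneSetCollection(sets=sets, names=names)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with atomic_write(path) as fh:
        for term in collection.term_ids:
            members = sorted(collection.sets[term])
            fh.write("\t".join([term, collection.names.get(term, term), *members]) + "\n")


def read_term_meta(path: str | Path) -> pd.DataFrame:
    """Term metadata side table: term_id, name, depth (TSV with header)."""
    meta = pd.read_csv(path, sep="\t", dtype={"term_id": str})
    required = {"term_id", "name", "depth"}
    if not required.issubset(meta.columns):
        raise FormatError(f"{path}: term metadata needs columns {sorted(required)}")
    if meta["term_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate term_id in metadata")
    return meta.set_index("term_id")


def write_term_meta(collection: GeneSetCollection, path: str | Path) -> None:
    with atomic_write(path) as fh:
        fh.write("term_id\tname\tdepth\n")
        for term in collection.term_ids:
            fh.write(f"{term}\t{collection.names.get(term, term)}\t{collection.depth[term]}\n")


def attach_depth(collection: GeneSetCollection, meta: pd.DataFrame) -> GeneSetCollection:
    depth = {t: int(meta.loc[t, "depth"]) for t in collection.term_ids if t in meta.index}
    names = dict(collection.names)
    for t in collection.term_ids:
        if t in meta.index:
            names[t] = str(meta.loc[t, "name"])
    return GeneSetCollection(sets=collection.sets, names=names, depth=depth, seed=collection.seed)


# ------------------------------------------------------------- studies/TSV

def write_study(study: ExpressionStudy, path: str | Path) -> None:
    """Signal matrix TSV: header row 1 = sample IDs, row 2 = group labels."""
    with atomic_write(path) as fh:
        fh.write("gene_id\t" + "\t".join(map(str, study.signal.columns)) + "\n")
        fh.write("group\t" + "\t".join(study.groups.loc[study.signal.columns]) + "\n")
        study.signal.to_csv(fh, sep="\t", header=False, float_format="%.6f")


def read_study(path: str | Path, study_id: str | None = None, label: str = "") -> ExpressionStudy:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        group_row = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2 or len(group_row) != len(header):
        raise FormatError(f"{path}: expected sample-ID and group-label header rows")
    samples = header[1:]
    groups = pd.Series(group_row[1:], index=samples)
    signal = pd.read_csv(path, sep="\t", skiprows=2, header=None, index_col=0, dtype={0: str})
    signal.columns = samples
    signal.index.name = "gene_id"
    if study_id is None:
        study_id = Path(path).stem
    return ExpressionStudy(study_id=study_id, signal=signal, groups=groups, label=label)


def read_probe_table(signal_path: str | Path, annotation_path: str | Path) -> ProbeTable:
    """Probe signal TSV (same layout as a study matrix, probes as rows)
    plus a two-column annotation TSV (probe_id, gene_id; repeated probe_id
    rows encode multi-annotation)."""
    study = read_study(signal_path, study_id="probes")
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    if list(ann.columns[:2]) != ["probe_id", "gene_id"]:
        raise FormatError(f"{annotation_path}: expected columns probe_id, gene_id")
    return ProbeTable(signal=study.signal, groups=study.groups, annotation=ann)


def write_differential(diff: DifferentialResult, path: str | Path) -> None:
    with atomic_write(path) as fh:
        table = diff.table.copy()
        table.insert(0, "study_id", diff.study_id)
        table.to_csv(fh, sep="\t", na_rep="NA")


def read_differential(path: str | Path) -> DifferentialResult:
    table = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if "study_id" not in table.columns or "log2fc" not in table.columns:
        raise FormatError(f"{path}: not a differential-result table")
    study_id = str(table["study_id"].iloc[0])
    return DifferentialResult(study_id=study_id, table=table.drop(columns="study_id"))


# ------------------------------------------------------------------ Z matrix

def write_zmatrix(zmat: ZScoreMatrix, path: str | Path) -> None:
    with atomic_write(path) as fh:
        zmat.z.to_csv(fh, sep="\t", na_rep="NA", float_format="%.6f")


def read_zmatrix(path: str | Path) -> ZScoreMatrix:
    z = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    z.index = z.index.astype(str)
    eff = z.notna().astype(int)  # effective sizes are not serialised; presence only
    return ZScoreMatrix(z=z, effective_sizes=eff, universe_sizes={})


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    with atomic_write(path) as fh:
        table.to_csv(fh, sep="\t", na_rep="NA")


def write_series(series: pd.Series, path: str | Path) -> None:
    with atomic_write(path) as fh:
        series.to_frame().to_csv(fh, sep="\t", na_rep="NA", float_format="%.6f")


def read_series(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    frame.index = frame.index.astype(str)
    return frame.iloc[:, 0]


# ---------------------------------------------------------------- JSON side

def write_json(obj, path: str | Path) -> None:
    with atomic_write(path) as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    write_json(truth.to_jsonable(), path)


def read_truth(path: str | Path) -> SyntheticTruth:
    return SyntheticTruth.from_jsonable(read_json(path))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
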