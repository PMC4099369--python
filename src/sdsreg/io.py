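"""Readers and writers: genotype/phenotype TSV and the GCTA binary GRM.

Formats
-------
Genotype TSV: header row of marker IDs, first column the sample ID, integer
codes; ploidy is chosen by the caller.  Missing or malformed cells are
rejected with their coordinates -- never silently imputed.

Phenotype TSV: either ``FID IID value`` (GCTA style; keyed on IID, FID is
written as a duplicate of IID) or a two-column ``ID value`` file.

GCTA binary GRM triple: ``<prefix>.grm.bin`` holds the lower triangle
including the diagonal, row-major by individual, as little-endian 4-byte
IEEE floats; ``<prefix>.grm.id`` has two whitespace-separated columns
(FID, IID); optional ``<prefix>.grm.N.bin`` holds the per-pair marker
counts in the same layout.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .relatedness import DIPLOID, HAPLOID, GenotypeMatrix, Grm
from .similarity import PhenotypePanel

logger = logging.getLogger(__name__)


def read_genotypes(path: str | Path, ploidy: str = DIPLOID) -> GenotypeMatrix:
    """Read a genotype TSV; reject duplicates, missing cells, illegal codes."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no marker columns found (malformed header?)")
    sample_ids = [str(s) for s in df.index]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample IDs {dupes[:5]}")
    marker_ids = [str(c) for c in df.columns]
    raw = df.to_numpy()
    codes = np.empty(raw.shape, dtype=np.int64)
    legal = {DIPLOID: {"0", "1", "2"}, HAPLOID: {"0", "1"}}[ploidy]
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                raise ValueError(
                    f"{path}: missing genotype at sample {sample_ids[i]!r}, "
                    f"marker {marker_ids[j]!r}"
                )
            cell = str(cell).strip()
            if cell not in legal:
                raise ValueError(
                    f"{path}: illegal {ploidy} code {cell!r} at sample "
                    f"{sample_ids[i]!r}, marker {marker_ids[j]!r}"
                )
            codes[i, j] = int(cell)
    if ploidy == DIPLOID and codes.max() <= 1:
        logger.warning(
            "%s: codes never exceed 1; the file may be haploid read as diploid", path
        )
    return GenotypeMatrix(
        codes=codes, ploidy=ploidy, sample_ids=sample_ids, marker_ids=marker_ids
    )


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        genotypes.codes, index=genotypes.sample_ids, columns=genotypes.marker_ids
    )
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_phenotypes(path: str | Path, trait_name: str = "trait") -> PhenotypePanel:
    """Read ``FID IID value`` or ``ID value`` whitespace/tab-separated files."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if df.shape[1] == 3:
        ids = [str(s) for s in df.iloc[:, 1]]
        vals = df.iloc[:, 2]
    elif df.shape[1] == 2:
        ids = [str(s) for s in df.iloc[:, 0]]
        vals = df.iloc[:, 1]
    else:
        raise ValueError(f"{path}: expected 2 or 3 columns, got {df.shape[1]}")
    try:
        y = vals.astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric phenotype value: {exc}") from exc
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sample IDs")
    return PhenotypePanel(y=y, sample_ids=ids, trait_name=trait_name)


def write_phenotypes(panel: PhenotypePanel, path: str | Path) -> None:
    """Write GCTA-style ``FID IID value`` (FID duplicated from IID)."""
    with open(path, "w") as fh:
        for sid, val in zip(panel.sample_ids, panel.y):
            fh.write(f"{sid}\t{sid}\t{float(val)!r}\n")


def _tri_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    # lower triangle including diagonal, row-major by individual
    return np.tril_indices(n)


def write_grm_gcta(grm: Grm, prefix: str | Path, n_markers: int | None = None) -> None:
    """Write the GCTA binary triple; N.bin records ``n_markers`` per pair."""
    prefix = str(prefix)
    n = grm.n
    rows, cols = _tri_indices(n)
    values = grm.theta[rows, cols].astype("<f4")
    values.tofile(prefix + ".grm.bin")
    with open(prefix + ".grm.id", "w") as fh:
        for sid in grm.sample_ids:
            fh.write(f"{sid}\t{sid}\n")
    if n_markers is not None:
        counts = np.full(values.size, float(n_markers), dtype="<f4")
        counts.tofile(prefix + ".grm.N.bin")


def read_grm_gcta(prefix: str | Path) -> Grm:
    """Read the GCTA binary triple; N.bin is optional and ignored if absent."""
    prefix = str(prefix)
    id_path = Path(prefix + ".grm.id")
    bin_path = Path(prefix + ".grm.bin")
    if not id_path.exists() or not bin_path.exists():
        raise FileNotFoundError(f"missing {prefix}.grm.id or {prefix}.grm.bin")
    ids = []
    with open(id_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise ValueError(f"{id_path}: expected two columns (FID IID)")
            ids.append(parts[1])
    n = len(ids)
    expected = n * (n + 1) // 2
    raw = np.fromfile(bin_path, dtype="<f4")
    if raw.size != expected:
        raise ValueError(
            f"{bin_path}: expected {expected} 4-byte floats "
            f"({expected * 4} bytes) for n={n}, found {raw.size} ({raw.size * 4} bytes)"
        )
    theta = np.zeros((n, n))
    rows, cols = _tri_indices(n)
    theta[rows, cols] = raw
    theta[cols, rows] = raw
    return Grm(theta=theta, sample_ids=ids, source="file")


def write_grm_tsv(grm: Grm, path: str | Path) -> None:
    """Plain dense TSV export of a GRM for inspection."""
    df = pd.DataFrame(grm.theta, index=grm.sample_ids, columns=grm.sample_ids)
    df.to_csv(path, sep="\t", index_label="sample_id")


def write_table(
    path: str | Path, df: pd.DataFrame, header_meta: dict[str, object] | None = None
) -> None:
    """Write a results TSV with ``#``-prefixed key=value metadata lines."""
    with open(path, "w") as fh:
        for key, val in (header_meta or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False)
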