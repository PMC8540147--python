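"""Readers and writers for the delimited tables and Newick trees.

Genotypes travel as a samples x markers table: first row marker ids, first
column sample ids, cells in {0, 1, 2, missing_token}.  All other tables are
headered delimited text.  Trees are serialized as Newick via scikit-bio.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .datatypes import (
    GenotypeMatrix,
    validate_gene_catalog,
    validate_marker_map,
    validate_sample_groups,
)

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "read_marker_map",
    "read_sample_groups",
    "read_gene_catalog",
    "read_vcf",
    "write_newick",
    "read_newick",
]

DEFAULT_MISSING = "NA"


class ParseError(ValueError):
    """Malformed input table."""


def _check_nonempty(path) -> None:
    if Path(path).stat().st_size == 0:
        raise ParseError(f"empty file: {path}")


def read_genotype_table(
    path, missing_token: str = DEFAULT_MISSING, delimiter: str = "\t"
) -> GenotypeMatrix:
    """Read a samples x markers dosage table.

    The header row carries marker ids (first cell is a corner label and is
    ignored); each following row is one sample.  Cells must be one of
    ``0``, ``1``, ``2`` or ``missing_token``.
    """
    _check_nonempty(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
        marker_ids = header[1:]
        n_markers = len(marker_ids)
        if n_markers == 0:
            raise ParseError(f"{path}: header has no marker columns")
        sample_ids: list[str] = []
        rows: list[np.ndarray] = []
        masks: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split(delimiter)
            if len(cells) != n_markers + 1:
                raise ParseError(
                    f"{path}: row {lineno} has {len(cells)} cells, expected {n_markers + 1}"
                )
            sample_ids.append(cells[0])
            dos = np.zeros(n_markers, dtype=np.int8)
            mask = np.zeros(n_markers, dtype=bool)
            for j, cell in enumerate(cells[1:]):
                if cell == missing_token:
                    mask[j] = True
                elif cell in ("0", "1", "2"):
                    dos[j] = int(cell)
                else:
                    raise ParseError(
                        f"{path}: invalid call {cell!r} at sample {cells[0]!r}, "
                        f"marker {marker_ids[j]!r}"
                    )
            rows.append(dos)
            masks.append(mask)
    if not rows:
        raise ParseError(f"{path}: no sample rows")
    return GenotypeMatrix(
        np.array(sample_ids, dtype=object),
        np.array(marker_ids, dtype=object),
        np.vstack(rows),
        np.vstack(masks),
    )


def write_genotype_table(
    gm: GenotypeMatrix, path, missing_token: str = DEFAULT_MISSING, delimiter: str = "\t"
) -> None:
    with open(path, "w") as fh:
        fh.write(delimiter.join(["sample_id", *map(str, gm.marker_ids)]) + "\n")
        for i, sid in enumerate(gm.sample_ids):
            cells = [
                missing_token if gm.missing_mask[i, j] else str(int(gm.dosages[i, j]))
                for j in range(gm.n_markers)
            ]
            fh.write(delimiter.join([str(sid), *cells]) + "\n")


def _read_table(path, delimiter: str = "\t") -> pd.DataFrame:
    _check_nonempty(path)
    return pd.read_csv(path, sep=delimiter, dtype={0: str})


def read_marker_map(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read marker_id / chromosome / position_cM."""
    return validate_marker_map(_read_table(path, delimiter))


def read_sample_groups(path, gm: GenotypeMatrix | None = None, delimiter: str = "\t") -> pd.DataFrame:
    """Read sample_id / group; if ``gm`` is given, ids must exist in it."""
    return validate_sample_groups(_read_table(path, delimiter), gm)


def read_gene_catalog(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read gene_id / chromosome / position_cM (slash-joined blocks allowed)."""
    return validate_gene_catalog(_read_table(path, delimiter))


def read_vcf(path) -> GenotypeMatrix:
    """Minimal VCF ingestion: biallelic records, GT field only.

    Requires cyvcf2.  Multi-allelic records are rejected; half-missing
    genotypes count as missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = np.array(vcf.samples, dtype=object)
    marker_ids, cols, masks = [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ParseError(f"multi-allelic record at {rec.CHROM}:{rec.POS}")
        marker_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        gt = np.asarray(rec.genotype.array())[:, :2]
        miss = (gt < 0).any(axis=1)
        dos = np.clip(gt, 0, 1).sum(axis=1)
        dos[miss] = 0
        cols.append(dos.astype(np.int8))
        masks.append(miss)
    if not cols:
        raise ParseError(f"{path}: no variant records")
    return GenotypeMatrix(
        sample_ids,
        np.array(marker_ids, dtype=object),
        np.column_stack(cols),
        np.column_stack(masks),
    )


def write_newick(tree: TreeNode, path) -> None:
    """Serialize a tree as Newick with branch lengths.

    skbio quotes leaf names containing reserved characters or spaces.
    """
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def tree_to_newick_string(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
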