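"""Region embeddings: mean-pooling of per-residue vectors and cosine distance.

A protein language model assigns each residue a D-dimensional vector (D = 1024
for ProtT5-class models); a disordered region is represented by the arithmetic
mean of its residues' vectors.  Computing the per-residue matrices is out of
scope — they are inputs, read from TSV (or produced by the mock embedder in
:mod:`idranno.simulate`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_DIM = 1024


@dataclass(frozen=True, order=True)
class SequenceRegion:
    """A contiguous protein interval, 1-based inclusive on both ends."""

    accession: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid region {self.accession}:{self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.accession, self.start, self.end)


class ResidueEmbeddingMatrix:
    """L x D matrix of residue vectors; row i is residue i+1 (1-based)."""

    def __init__(self, accession: str, matrix: np.ndarray) -> None:
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2:
            raise ValueError(f"{accession}: embedding matrix must be 2-D")
        if not np.all(np.isfinite(matrix)):
            raise ValueError(f"{accession}: embedding matrix has non-finite values")
        self.accession = accession
        self.matrix = matrix

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class RegionEmbedding:
    """A region together with its pooled D-vector."""

    region: SequenceRegion
    vector: np.ndarray

    def __post_init__(self) -> None:
        vec = np.asarray(self.vector, dtype=np.float64)
        if vec.ndim != 1 or not np.all(np.isfinite(vec)):
            raise ValueError(
                f"region {self.region.key}: embedding vector must be a finite 1-D array"
            )
        object.__setattr__(self, "vector", vec)


def pool_region(
    matrix: ResidueEmbeddingMatrix, region: SequenceRegion
) -> RegionEmbedding:
    """Mean-pool the residue vectors of ``region`` into one D-vector."""
    if region.accession != matrix.accession:
        raise ValueError(
            f"region accession {region.accession!r} does not match "
            f"matrix accession {matrix.accession!r}"
        )
    if region.end > matrix.length:
        raise ValueError(
            f"region {region.accession}:{region.start}-{region.end} exceeds "
            f"matrix bounds (L={matrix.length})"
        )
    rows = matrix.matrix[region.start - 1 : region.end]
    return RegionEmbedding(region=region, vector=rows.mean(axis=0))


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cos(u, v), in [0, 2].  Zero-norm inputs are degenerate embeddings."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine distance undefined for a zero-norm vector")
    return float(1.0 - np.dot(u, v) / (nu * nv))


# -- I/O ---------------------------------------------------------------------
#
# Residue-matrix TSV: columns accession, residue_index (1-based), d1..dD.
# Region-embedding TSV: columns accession, start, end, d1..dD.
# Values are written with repr-precision doubles so round-trips are bit-exact.


def write_residue_matrices(matrices: dict[str, ResidueEmbeddingMatrix], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        dim = next(iter(matrices.values())).dim if matrices else 0
        header = ["accession", "residue_index"] + [f"d{i+1}" for i in range(dim)]
        fh.write("\t".join(header) + "\n")
        for acc in sorted(matrices):
            mat = matrices[acc]
            for i in range(mat.length):
                row = [acc, str(i + 1)] + [repr(float(x)) for x in mat.matrix[i]]
                fh.write("\t".join(row) + "\n")


def read_residue_matrices(path) -> dict[str, ResidueEmbeddingMatrix]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    dims = [c for c in df.columns if c.startswith("d") and c[1:].isdigit()]
    out: dict[str, ResidueEmbeddingMatrix] = {}
    for acc, grp in df.groupby("accession", sort=True):
        grp = grp.sort_values("residue_index")
        idx = grp["residue_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise ValueError(f"{acc}: residue indices must be 1..L without gaps")
        out[str(acc)] = ResidueEmbeddingMatrix(str(acc), grp[dims].to_numpy())
    return out


def write_region_embeddings(embeddings: list[RegionEmbedding], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        dim = embeddings[0].vector.size if embeddings else 0
        header = ["accession", "start", "end"] + [f"d{i+1}" for i in range(dim)]
        fh.write("\t".join(header) + "\n")
        for emb in sorted(embeddings, key=lambda e: e.region.key):
            row = [emb.region.accession, str(emb.region.start), str(emb.region.end)]
            row += [repr(float(x)) for x in emb.vector]
            fh.write("\t".join(row) + "\n")


def read_region_embeddings(path) -> list[RegionEmbedding]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    dims = [c for c in df.columns if c.startswith("d") and c[1:].isdigit()]
    out = []
    for rec in df.itertuples(index=False):
        region = SequenceRegion(str(rec.accession), int(rec.start), int(rec.end))
        out.append(RegionEmbedding(region, np.array([getattr(rec, c) for c in dims])))
    return out


def write_residue_matrices_h5(
    matrices: dict[str, ResidueEmbeddingMatrix], path
) -> None:
    """HDF5 container: one float64 dataset per accession at the root.

    Layout: dataset name = accession, shape (L, D), row i = residue i+1,
    little-endian IEEE-754 doubles — readable from any language with an
    HDF5 binding.  The TSV format is the plain-text fallback.
    """
    import h5py

    with h5py.File(path, "w") as fh:
        for acc in sorted(matrices):
            fh.create_dataset(acc, data=matrices[acc].matrix, dtype="<f8")


def read_residue_matrices_h5(path) -> dict[str, ResidueEmbeddingMatrix]:
    import h5py

    out: dict[str, ResidueEmbeddingMatrix] = {}
    with h5py.File(path, "r") as fh:
        for acc in fh:
            out[str(acc)] = ResidueEmbeddingMatrix(str(acc), fh[acc][()])
    return out


def read_fasta_lengths(path) -> dict[str, int]:
    """Sequence lengths keyed by accession, for validating matrix sizes."""
    from Bio import SeqIO

    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def validate_matrix_lengths(
    matrices: dict[str, ResidueEmbeddingMatrix], lengths: dict[str, int]
) -> None:
    """Hard-error when a matrix row count disagrees with the sequence length."""
    for acc, mat in matrices.items():
        if acc in lengths and lengths[acc] != mat.length:
            raise ValueError(
                f"{acc}: embedding matrix has {mat.length} rows but the "
                f"sequence has {lengths[acc]} residues"
            )
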