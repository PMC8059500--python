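"""Joint site-frequency spectrum container and text IO.

A joint SFS over two populations is a ``(n1+1) x (n2+1)`` matrix of site
counts indexed by the derived- (unfolded) or minor- (folded) allele count in
each population, where ``n1``/``n2`` are haploid sample sizes.  The
``(0, 0)`` and ``(n1, n2)`` corner cells are structurally empty for an
unfolded spectrum (such sites are not segregating in the sample).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["JointSFS"]


class JointSFS:
    """Matrix of allele-count pairs for two populations.

    Parameters
    ----------
    matrix : array-like of shape (n1+1, n2+1)
        Non-negative site counts (or projected fractional weights).
    folded : bool
        Whether entries are indexed by minor-allele configuration.
    """

    def __init__(self, matrix, folded: bool = False):
        mat = np.asarray(matrix)
        if mat.ndim != 2:
            raise ValueError("joint SFS must be a 2-D matrix")
        if (mat < 0).any():
            raise ValueError("SFS counts must be non-negative")
        self.matrix = mat
        self.folded = bool(folded)

    @property
    def n1(self) -> int:
        """Haploid sample size of population 1."""
        return self.matrix.shape[0] - 1

    @property
    def n2(self) -> int:
        return self.matrix.shape[1] - 1

    @property
    def n_sites(self) -> float:
        return float(self.matrix.sum())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, JointSFS)
            and self.folded == other.folded
            and self.matrix.shape == other.matrix.shape
            and np.array_equal(self.matrix, other.matrix)
        )

    def __repr__(self) -> str:
        kind = "folded" if self.folded else "unfolded"
        return (f"JointSFS(n1={self.n1}, n2={self.n2}, {kind}, "
                f"sites={self.n_sites:g})")

    def fold(self) -> "JointSFS":
        """Fold onto minor-allele configurations.

        Cell ``(i, j)`` is merged with ``(n1-i, n2-j)``; the mass lands on
        whichever of the two has the smaller total allele count (the minor
        configuration), with the lexicographically smaller index pair as the
        tie-break when the totals are equal.  Folding twice is a no-op.
        """
        if self.folded:
            return JointSFS(self.matrix.copy(), folded=True)
        n1, n2 = self.n1, self.n2
        out = np.zeros_like(self.matrix, dtype=float)
        for i in range(n1 + 1):
            for j in range(n2 + 1):
                ci, cj = n1 - i, n2 - j
                if (i + j, i, j) <= (ci + cj, ci, cj):
                    out[i, j] += self.matrix[i, j]
                else:
                    out[ci, cj] += self.matrix[i, j]
        if np.issubdtype(self.matrix.dtype, np.integer):
            out = out.astype(self.matrix.dtype)
        return JointSFS(out, folded=True)

    def mass_vector(self, drop_corners: bool = True) -> np.ndarray:
        """Flattened spectrum normalized to unit mass.

        The (0,0) and (n1,n2) corners are excluded before normalization by
        default — they carry no segregating-site information.  An all-zero
        spectrum maps to the zero vector.
        """
        mat = self.matrix.astype(float).copy()
        if drop_corners:
            mat[0, 0] = 0.0
            mat[-1, -1] = 0.0
        vec = mat.ravel()
        total = vec.sum()
        return vec / total if total > 0 else vec

    # ---- text formats -------------------------------------------------

    def to_dadi(self, path) -> None:
        """Write in dadi-style plain text: a dimension header line
        (``n1+1 n2+1 folded|unfolded``) then the row-major cell values."""
        kind = "folded" if self.folded else "unfolded"
        with open(path, "w") as fh:
            fh.write(f"{self.n1 + 1} {self.n2 + 1} {kind}\n")
            fh.write(" ".join(f"{v:g}" for v in self.matrix.ravel()) + "\n")

    @classmethod
    def from_dadi(cls, path) -> "JointSFS":
        text = Path(path).read_text().split("\n")
        head = text[0].split()
        d1, d2 = int(head[0]), int(head[1])
        folded = len(head) > 2 and head[2] == "folded"
        vals = np.array([float(v) for v in text[1].split()])
        if vals.size != d1 * d2:
            raise ValueError("SFS value count does not match header dimensions")
        if np.allclose(vals, np.round(vals)):
            vals = np.round(vals).astype(np.int64)
        return cls(vals.reshape(d1, d2), folded=folded)

    def to_tsv(self, path) -> None:
        """Write as TSV with row/column labels (allele counts)."""
        with open(path, "w") as fh:
            fh.write("d1\\d2\t" + "\t".join(map(str, range(self.n2 + 1))) + "\n")
            for i in range(self.n1 + 1):
                row = "\t".join(f"{v:g}" for v in self.matrix[i])
                fh.write(f"{i}\t{row}\n")
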