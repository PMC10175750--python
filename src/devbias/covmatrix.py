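"""Labeled symmetric covariance matrices: the central currency.

A :class:`CovMatrix` carries a D/P/G/R/M/E label, the taxon it was
estimated in, optional rank metadata for reduced-rank fits, and a
``scale_factor`` bookkeeping entry (coordinates multiplied by 10,000 before
REML fitting are recorded here; stored matrices are always on the original
coordinate scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

LABELS = ("D", "P", "G", "R", "M", "E")

#: relative eigenvalue threshold used both for the PSD check and for
#: counting the numerical rank of reduced-rank fits
EIG_TOL = 1e-8


@dataclass
class CovMatrix:
    matrix: np.ndarray
    label: str = "D"
    taxon: str = ""
    rank: int | None = None
    scale_factor: float = 1.0
    source: str = ""
    validate: bool = True
    is_psd: bool = True

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"matrix must be square; got {m.shape}")
        scale = max(float(np.abs(m).max()), 1e-300)
        asym = float(np.abs(m - m.T).max())
        if asym > 1e-8 * scale:
            raise ValueError(f"matrix is asymmetric (max |A - A^T| = {asym:g})")
        m = (m + m.T) / 2.0
        self.matrix = m
        w = np.linalg.eigvalsh(m)
        lam_max = max(float(w[-1]), 0.0)
        self.is_psd = bool(w[0] >= -EIG_TOL * max(lam_max, 1e-300))
        if self.validate:
            if self.label not in LABELS:
                raise ValueError(f"label must be one of {LABELS}")
            if not self.is_psd:
                raise ValueError(
                    f"matrix is not PSD within tolerance (min eig {w[0]:g})"
                )
        if self.rank is None:
            self.rank = int(np.sum(w > EIG_TOL * max(lam_max, 1e-300)))

    @property
    def p(self) -> int:
        return self.matrix.shape[0]

    @property
    def trace(self) -> float:
        return float(np.trace(self.matrix))

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues in descending order."""
        return np.linalg.eigvalsh(self.matrix)[::-1]

    def scaled(self, c: float) -> "CovMatrix":
        return CovMatrix(self.matrix * c, label=self.label, taxon=self.taxon,
                         rank=self.rank, scale_factor=self.scale_factor,
                         source=self.source, validate=False)

    # ------------------------------------------------------------------ I/O

    @staticmethod
    def coordinate_names(p: int) -> list[str]:
        if p % 2 == 0:
            return [f"{ax}{i}" for i in range(1, p // 2 + 1) for ax in ("x", "y")]
        return [f"v{i}" for i in range(1, p + 1)]

    def to_csv(self, path: str | Path) -> None:
        names = self.coordinate_names(self.p)
        with open(path, "w") as fh:
            fh.write(f"#label={self.label}\n")
            fh.write(f"#taxon={self.taxon}\n")
            fh.write(f"#rank={self.rank}\n")
            fh.write(f"#scale_factor={self.scale_factor:g}\n")
            if self.source:
                fh.write(f"#source={self.source}\n")
            fh.write("," + ",".join(names) + "\n")
            for name, row in zip(names, self.matrix):
                fh.write(name + "," + ",".join(f"{v:.12e}" for v in row) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path, validate: bool = True) -> "CovMatrix":
        meta: dict[str, str] = {}
        rows: list[list[float]] = []
        header_seen = False
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "=" in line:
                        key, value = line[1:].split("=", 1)
                        meta[key.strip()] = value.strip()
                    continue
                cells = line.split(",")
                if not header_seen:
                    header_seen = True      # column-name row
                    continue
                rows.append([float(v) for v in cells[1:]])
        if not rows:
            raise ValueError(f"{path}: no matrix block found")
        rank = meta.get("rank")
        return cls(
            matrix=np.array(rows),
            label=meta.get("label", "D"),
            taxon=meta.get("taxon", ""),
            rank=None if rank in (None, "", "None") else int(rank),
            scale_factor=float(meta.get("scale_factor", 1.0)),
            source=meta.get("source", str(path)),
            validate=validate,
        )
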