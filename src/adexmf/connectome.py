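"""Structural connectomes: synthetic generation and plain-text I/O.

The on-disk layout is the conventional connectivity bundle: a directory (or
zip archive) holding ``weights.txt``, ``tract_lengths.txt`` and
``centres.txt``, all whitespace-delimited.
"""
from __future__ import annotations

import logging
import zipfile
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np

__all__ = [
    "Connectome",
    "ConnectomeFormatError",
    "generate_synthetic_connectome",
    "read_connectome",
    "write_connectome",
]

logger = logging.getLogger(__name__)

_FILES = ("weights.txt", "tract_lengths.txt", "centres.txt")


class ConnectomeFormatError(ValueError):
    """Raised when an on-disk connectome bundle is malformed."""


@dataclass
class Connectome:
    """A weighted, distance-annotated parcellation of cortical regions.

    ``weights[j, k]`` is the dimensionless coupling strength from region *j*
    to region *k*, with unit self-coupling on the diagonal.
    ``tract_lengths`` holds symmetric inter-region distances in mm.
    """

    weights: np.ndarray
    tract_lengths: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.tract_lengths = np.asarray(self.tract_lengths, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n) or self.tract_lengths.shape != (n, n):
            raise ValueError(
                f"weights {self.weights.shape} and tract_lengths "
                f"{self.tract_lengths.shape} must be square and equal-shaped"
            )
        if not (np.isfinite(self.weights).all() and np.isfinite(self.tract_lengths).all()):
            raise ValueError("connectome matrices must be finite")
        if (self.weights < 0).any() or (self.tract_lengths < 0).any():
            raise ValueError("connectome matrices must be nonnegative")
        if not np.array_equal(np.diag(self.weights), np.ones(n)):
            raise ValueError("weights must have a unit diagonal")
        if not np.allclose(self.tract_lengths, self.tract_lengths.T, atol=1e-9):
            raise ValueError("tract_lengths must be symmetric")
        if np.diag(self.tract_lengths).any():
            raise ValueError("tract_lengths must have a zero diagonal")
        if not self.labels:
            self.labels = [f"R{i:03d}" for i in range(n)]
        if len(self.labels) != n:
            raise ValueError("label count must match region count")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


def generate_synthetic_connectome(
    n_regions: int,
    density: float = 1.0,
    seed: int = 0,
    log_mu: float = -2.0,
    log_sigma: float = 1.0,
    box_mm: float = 100.0,
    mean_in_strength: float = 1.0,
) -> Connectome:
    """Generate a random connectome with tractography-like statistics.

    Region centres are sampled uniformly in a ``box_mm`` cube, so tract
    lengths are genuine Euclidean distances (hence symmetric and triangle-
    inequality consistent).  Off-diagonal weights are symmetric log-normal
    draws with a ``(1 - density)`` fraction of region pairs removed,
    rescaled so the mean off-diagonal column sum equals
    ``mean_in_strength`` — this pins the physical meaning of the coupling
    strength ``S`` regardless of region count or density.  Deterministic
    for a fixed seed.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be at least 2")
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    if mean_in_strength <= 0:
        raise ValueError("mean_in_strength must be positive")
    rng = np.random.default_rng(seed)

    centres = rng.uniform(0.0, box_mm, size=(n_regions, 3))
    diff = centres[:, None, :] - centres[None, :, :]
    lengths = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(lengths, 0.0)

    w = np.exp(rng.normal(log_mu, log_sigma, size=(n_regions, n_regions)))
    w = np.triu(w, k=1)
    w = w + w.T
    if density < 1.0:
        iu, ju = np.triu_indices(n_regions, k=1)
        n_pairs = iu.size
        n_zero = int(round((1.0 - density) * n_pairs))
        if n_zero:
            drop = rng.choice(n_pairs, size=n_zero, replace=False)
            w[iu[drop], ju[drop]] = 0.0
            w[ju[drop], iu[drop]] = 0.0
    mean_colsum = w.sum(axis=0).mean()
    if mean_colsum > 0:
        w *= mean_in_strength / mean_colsum
    np.fill_diagonal(w, 1.0)

    labels = [f"R{i:03d}" for i in range(n_regions)]
    conn = Connectome(w, lengths, labels)
    conn.centres = centres
    return conn


def _parse_matrix(text: str, name: str) -> np.ndarray:
    try:
        mat = np.loadtxt(StringIO(text), ndmin=2)
    except ValueError as exc:
        raise ConnectomeFormatError(f"{name}: unreadable matrix ({exc})") from exc
    if mat.shape[0] != mat.shape[1]:
        raise ConnectomeFormatError(f"{name}: expected a square matrix, got {mat.shape}")
    if not np.isfinite(mat).all():
        raise ConnectomeFormatError(f"{name}: contains non-finite entries")
    if (mat < 0).any():
        raise ConnectomeFormatError(f"{name}: contains negative entries")
    return mat


def _read_bundle_texts(path: Path) -> dict:
    texts = {}
    if path.is_dir():
        for fname in _FILES:
            fpath = path / fname
            if fpath.exists():
                texts[fname] = fpath.read_text()
    elif zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            for member in zf.namelist():
                base = Path(member).name
                if base in _FILES:
                    texts[base] = zf.read(member).decode()
    else:
        raise ConnectomeFormatError(f"{path}: not a directory or zip archive")
    return texts


def read_connectome(path) -> Connectome:
    """Read a connectome bundle from a directory or zip archive.

    A non-unit weight diagonal is coerced to 1 with a logged warning; any
    other contract violation raises :class:`ConnectomeFormatError` naming
    the offending file.
    """
    path = Path(path)
    if not path.exists():
        raise ConnectomeFormatError(f"{path}: no such file or directory")
    texts = _read_bundle_texts(path)
    for required in ("weights.txt", "tract_lengths.txt"):
        if required not in texts:
            raise ConnectomeFormatError(f"{path}: missing {required}")

    weights = _parse_matrix(texts["weights.txt"], "weights.txt")
    lengths = _parse_matrix(texts["tract_lengths.txt"], "tract_lengths.txt")
    if weights.shape != lengths.shape:
        raise ConnectomeFormatError(
            f"weights.txt {weights.shape} and tract_lengths.txt {lengths.shape} "
            "have mismatched shapes"
        )
    if not np.allclose(lengths, lengths.T, atol=1e-9):
        raise ConnectomeFormatError("tract_lengths.txt: matrix is not symmetric")
    np.fill_diagonal(lengths, 0.0)

    diag = np.diag(weights)
    if not np.array_equal(diag, np.ones(len(diag))):
        logger.warning(
            "weights.txt: diagonal is not all 1 (min %.3g, max %.3g); coercing to 1",
            diag.min(),
            diag.max(),
        )
        np.fill_diagonal(weights, 1.0)

    labels = []
    centres = None
    if "centres.txt" in texts:
        rows = [ln.split() for ln in texts["centres.txt"].splitlines() if ln.strip()]
        if rows:
            labels = [r[0] for r in rows]
            try:
                centres = np.array([[float(x) for x in r[1:4]] for r in rows])
            except (ValueError, IndexError):
                centres = None
            if len(labels) != weights.shape[0]:
                raise ConnectomeFormatError(
                    f"centres.txt: {len(labels)} rows for {weights.shape[0]} regions"
                )

    conn = Connectome(weights, lengths, labels)
    if centres is not None:
        conn.centres = centres
    return conn


def write_connectome(conn: Connectome, path) -> None:
    """Write a connectome bundle (directory layout) readable by
    :func:`read_connectome`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savetxt(path / "weights.txt", conn.weights, fmt="%.17g")
    np.savetxt(path / "tract_lengths.txt", conn.tract_lengths, fmt="%.17g")
    centres = getattr(conn, "centres", None)
    if centres is None:
        centres = np.zeros((conn.n_regions, 3))
    lines = [
        f"{label} " + " ".join(f"{x:.17g}" for x in xyz)
        for label, xyz in zip(conn.labels, centres)
    ]
    (path / "centres.txt").write_text("\n".join(lines) + "\n")
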