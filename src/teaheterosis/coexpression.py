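"""Co-expression module discovery on genotype-mean profiles.

Genes up-regulated in the hybrids are clustered on a small self-organizing
map (SOM): a rows x cols grid of prototype vectors trained by the batch
algorithm with a Gaussian neighborhood whose radius decays linearly over
epochs.  Each gene maps to its best-matching unit (BMU); genes sharing a
unit form an expression module.  Transcription factors co-located with an
anchor pathway gene are module co-regulation candidates.  Pairwise Pearson
correlations over the (few) genotype means get exact two-sided p-values via
the t transform t = r*sqrt(n-2)/sqrt(1-r^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SomModel:
    """Trained SOM codebook on a (rows x cols) grid.

    ``codebook`` has shape (rows*cols, dim); unit (r, c) is row r*cols + c.
    ``quantization_errors`` holds the mean BMU distance after each epoch.
    """

    rows: int
    cols: int
    codebook: np.ndarray
    epochs: int
    seed: int
    quantization_errors: list[float] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    def unit_coords(self) -> np.ndarray:
        """(n_units, 2) array of (row, col) grid coordinates."""
        return np.array(
            [(r, c) for r in range(self.rows) for c in range(self.cols)], dtype=float
        )

    @property
    def quantization_error(self) -> float:
        return self.quantization_errors[-1] if self.quantization_errors else float("nan")


@dataclass
class ModuleAssignment:
    """gene id -> flat unit index, with grid shape for coordinate lookup."""

    rows: int
    cols: int
    unit_of: dict[str, int]

    def coords(self, gene: str) -> tuple[int, int]:
        u = self.unit_of[gene]
        return divmod(u, self.cols)

    def members(self, unit: int) -> set[str]:
        return {g for g, u in self.unit_of.items() if u == unit}

    def unit_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for u in self.unit_of.values():
            counts[u] = counts.get(u, 0) + 1
        return counts


@dataclass
class CorrelationMatrix:
    ids: list[str]
    r: np.ndarray
    p: np.ndarray
    n: int

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.ids):
            for j, b in enumerate(self.ids):
                if j <= i:
                    continue
                rows.append({"a": a, "b": b, "r": self.r[i, j], "p": self.p[i, j],
                             "n": self.n})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def zscore_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row (gene) of a genes x conditions profile table.

    Flat rows (zero variance) become all-zero rather than NaN so they can
    still be assigned to a unit.
    """
    arr = profiles.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    out = np.where(sd > 0, (arr - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(out, index=profiles.index, columns=profiles.columns)


def _as_matrix(profiles: Mapping[str, Sequence[float]] | pd.DataFrame) -> tuple[list[str], np.ndarray]:
    if isinstance(profiles, pd.DataFrame):
        ids = [str(g) for g in profiles.index]
        x = profiles.to_numpy(dtype=float)
    else:
        ids = [str(g) for g in profiles]
        x = np.asarray([profiles[g] for g in profiles], dtype=float)
    for gid, row in zip(ids, x):
        if not np.isfinite(row).all():
            raise ValueError(f"non-finite profile for gene {gid!r}")
    return ids, x


# ---------------------------------------------------------------------------
# batch SOM
# ---------------------------------------------------------------------------

def _farthest_first_init(
    x: np.ndarray, n_units: int, rng: np.random.Generator
) -> np.ndarray:
    """Seed the codebook by farthest-first traversal of the input profiles.

    The first prototype is a seed-chosen random profile; each subsequent one
    is the profile farthest from all prototypes chosen so far.  Spreads the
    initial codebook across well-separated clusters, avoiding dead units.
    """
    first = int(rng.integers(len(x)))
    chosen = [first]
    d2 = ((x - x[first]) ** 2).sum(axis=1)
    while len(chosen) < n_units:
        nxt = int(d2.argmax())
        chosen.append(nxt)
        d2 = np.minimum(d2, ((x - x[nxt]) ** 2).sum(axis=1))
    return x[chosen].astype(float).copy()


def train_som(
    profiles: Mapping[str, Sequence[float]] | pd.DataFrame,
    rows: int = 2,
    cols: int = 4,
    epochs: int = 20,
    seed: int = 0,
    sigma0: float = 0.75,
) -> SomModel:
    """Train a batch SOM on gene profiles.

    The codebook is initialised by farthest-first traversal of the input
    profiles (seed-chosen start).  Each epoch computes every gene's BMU,
    then replaces every unit's prototype by the neighborhood-weighted mean
    of all genes, with Gaussian weights exp(-d^2 / (2 sigma^2)) on grid
    distance d and sigma decaying linearly from ``sigma0`` to ~0.  The
    default ``sigma0`` of 0.75 unit spacings suits the small grids used for
    expression-module screening; raise it toward max(rows, cols)/2 for
    larger maps.  Deterministic given the seed.
    """
    if rows < 1 or cols < 1:
        raise ValueError("grid must have at least one unit")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    ids, x = _as_matrix(profiles)
    if len(ids) == 0:
        raise ValueError("no input genes")
    if x.shape[1] < 2:
        raise ValueError("profile dimension must be >= 2")
    n_units = rows * cols
    rng = np.random.default_rng(seed)
    codebook = _farthest_first_init(x, n_units, rng)
    coords = np.array(
        [(r, c) for r in range(rows) for c in range(cols)], dtype=float
    )
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    qes: list[float] = []
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        sigma = max(sigma0 * (1.0 - frac), 0.1)
        d2 = ((x[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
        bmu = d2.argmin(axis=1)
        qes.append(float(np.sqrt(d2[np.arange(len(ids)), bmu]).mean()))
        h = np.exp(-grid_d2 / (2.0 * sigma**2))  # (units, units)
        w = h[:, bmu]  # (units, genes): weight of gene g for unit u
        denom = w.sum(axis=1, keepdims=True)
        updated = (w @ x) / np.where(denom > 0, denom, 1.0)
        codebook = np.where(denom > 0, updated, codebook)
    # final quantization error with the trained codebook
    d2 = ((x[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    qes.append(float(np.sqrt(d2.min(axis=1)).mean()))
    return SomModel(
        rows=rows, cols=cols, codebook=codebook, epochs=epochs, seed=seed,
        quantization_errors=qes,
    )


def assign_modules(
    model: SomModel,
    profiles: Mapping[str, Sequence[float]] | pd.DataFrame,
) -> ModuleAssignment:
    """Map each gene to its best-matching unit (ties -> lowest unit index)."""
    ids, x = _as_matrix(profiles)
    if x.shape[1] != model.codebook.shape[1]:
        raise ValueError(
            f"profile dimension {x.shape[1]} does not match codebook "
            f"dimension {model.codebook.shape[1]}"
        )
    d2 = ((x[:, None, :] - model.codebook[None, :, :]) ** 2).sum(axis=2)
    bmu = d2.argmin(axis=1)  # argmin returns the lowest index on ties
    return ModuleAssignment(
        rows=model.rows, cols=model.cols,
        unit_of={g: int(u) for g, u in zip(ids, bmu)},
    )


def co_module_candidates(
    assignment: ModuleAssignment,
    anchors: set[str] | Sequence[str],
    tf_ids: set[str] | Sequence[str],
) -> dict[str, set[str]]:
    """Transcription factors sharing a SOM unit with each anchor gene.

    TF identity is an input list; screening is set intersection with the
    anchor's module members (the anchor itself excluded).  An anchor alone
    in its unit yields an empty set.
    """
    anchors = set(map(str, anchors))
    tf_ids = set(map(str, tf_ids))
    missing = anchors - set(assignment.unit_of)
    if missing:
        raise KeyError(f"anchor gene(s) not in assignment: {sorted(missing)}")
    out: dict[str, set[str]] = {}
    for anchor in sorted(anchors):
        members = assignment.members(assignment.unit_of[anchor])
        out[anchor] = (members & tf_ids) - {anchor}
    return out


# ---------------------------------------------------------------------------
# Pearson correlation with exact small-n p-values
# ---------------------------------------------------------------------------

def correlation_p(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation of r over n observations.

    Uses t = r*sqrt(n-2)/sqrt(1-r^2) with n-2 degrees of freedom; |r| = 1
    gives p = 0 exactly.
    """
    if n < 3:
        raise ValueError("need at least 3 observations")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlation_matrix(
    profiles: Mapping[str, Sequence[float]] | pd.DataFrame,
) -> CorrelationMatrix:
    """All-pairs Pearson r and two-sided p over equally long value vectors."""
    ids, x = _as_matrix(profiles)
    n = x.shape[1]
    if n < 3:
        raise ValueError("need at least 3 observations per profile")
    r = np.atleast_2d(np.corrcoef(x))
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)  # exact symmetry to the last bit
    np.fill_diagonal(r, 1.0)
    m = len(ids)
    p = np.ones((m, m))
    for i in range(m):
        p[i, i] = 0.0
        for j in range(i + 1, m):
            pv = correlation_p(float(r[i, j]), n)
            p[i, j] = p[j, i] = pv
    return CorrelationMatrix(ids=ids, r=r, p=p, n=n)
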