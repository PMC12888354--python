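"""Bootstrap stability of hypergraph centrality measures.

The network pipeline is re-run on resampled data and each replicate's
centralities are compared with the original via Spearman rank correlation
(the stability index r_s).  Two resampling schemes are implemented:

* ``matrix_nodes`` (default): the rows/columns of the association matrix
  are resampled with replacement and collapsed to the unique node set drawn
  (a duplicated node adds no structure to an unweighted graph); the
  hypergraph and centralities are rebuilt on the submatrix.
* ``subjects``: subjects are resampled with replacement and the association
  matrix is rebuilt from scratch — the conventional network-psychometrics
  case bootstrap.

An ``identity`` scheme that returns the original network unchanged is kept
as a test hook.  Replicates whose unique node set is smaller than 2, or
whose index is undefined (fewer than 3 shared defined nodes, or a constant
centrality vector), are recorded as degenerate and excluded from summaries
with their count reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationMatrix, MissingPolicy, build_matrix
from .centrality import MEASURES, hypergraph_centrality
from .netbuild import build_hypergraph
from .synthetic import CohortTable

__all__ = [
    "BootstrapResult",
    "bootstrap_centrality",
    "stability_index",
    "summarize_stability",
    "stability_analysis",
]

DEFAULT_B = 500


def _centralities(matrix: AssociationMatrix, threshold: float, mode: str,
                  representation: str) -> dict[str, pd.Series]:
    h = build_hypergraph(matrix, threshold, mode)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {m: hypergraph_centrality(h, m, representation) for m in MEASURES}


@dataclass
class BootstrapResult:
    """Original and per-replicate centrality vectors plus bookkeeping."""

    original: dict[str, pd.Series]
    replicates: list[dict[str, pd.Series]]
    n_degenerate: int = 0
    scheme: str = "matrix_nodes"

    @property
    def B(self) -> int:
        return len(self.replicates)


def bootstrap_centrality(
    source: CohortTable | AssociationMatrix,
    B: int = DEFAULT_B,
    scheme: str = "matrix_nodes",
    threshold: float = 0.2,
    seed: int | None = None,
    mode: str = "maximal_clique",
    representation: str = "two_section",
    policy: MissingPolicy | None = None,
) -> BootstrapResult:
    """Recompute hypergraph centralities on ``B`` bootstrap replicates.

    Each replicate draws from an independent substream of the master seed,
    so the full replicate set is reproducible and insensitive to B.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if scheme not in ("matrix_nodes", "subjects", "identity"):
        raise ValueError(f"unknown scheme {scheme!r}")

    if isinstance(source, AssociationMatrix):
        matrix = source
        cohort = None
        if scheme == "subjects":
            raise ValueError("subjects scheme needs a CohortTable, not a matrix")
    else:
        cohort = source
        matrix = build_matrix(cohort, policy=policy)

    original = _centralities(matrix, threshold, mode, representation)
    streams = np.random.SeedSequence(seed).spawn(B)

    replicates: list[dict[str, pd.Series]] = []
    n_degenerate = 0
    p = matrix.p
    for ss in streams:
        rng = np.random.default_rng(ss)
        if scheme == "identity":
            replicates.append(original)
            continue
        if scheme == "matrix_nodes":
            drawn = rng.integers(0, p, size=p)
            keep_idx = sorted(set(drawn.tolist()))
            if len(keep_idx) < 2:
                n_degenerate += 1
                continue
            sub = matrix.subset([matrix.variables[k] for k in keep_idx])
            replicates.append(_centralities(sub, threshold, mode, representation))
        else:  # subjects
            rows = rng.integers(0, cohort.n, size=cohort.n)
            boot = CohortTable(
                cohort.data.iloc[rows].reset_index(drop=True), cohort.specs
            )
            try:
                sub = build_matrix(boot, policy=policy)
            except ValueError:
                n_degenerate += 1
                continue
            replicates.append(_centralities(sub, threshold, mode, representation))
    return BootstrapResult(original, replicates, n_degenerate, scheme)


def stability_index(original: pd.Series, replicate: pd.Series) -> float:
    """Spearman correlation over the shared, defined nodes (ties mid-ranked).

    NaN when fewer than 3 nodes are shared and defined, or when either
    restricted vector is constant (rank correlation undefined).
    """
    shared = original.index.intersection(replicate.index)
    a = original.loc[shared]
    b = replicate.loc[shared]
    keep = a.notna() & b.notna()
    a, b = a[keep], b[keep]
    if len(a) < 3 or a.nunique() == 1 or b.nunique() == 1:
        return float("nan")
    if np.array_equal(a.to_numpy(), b.to_numpy()):
        return 1.0
    return float(stats.spearmanr(a, b).statistic)


def summarize_stability(indices: pd.DataFrame) -> pd.DataFrame:
    """Distribution summary of per-replicate stability indices.

    ``indices`` has one column per measure and one row per replicate.
    Returns one row per measure plus a pooled row across measures: mean,
    sample SD, median, P25/P75 (linear interpolation), min, max, and the
    number of valid (non-NaN) indices.
    """
    if indices.empty:
        raise ValueError("no replicates to summarize")

    def row(x: pd.Series) -> dict:
        x = x.dropna().to_numpy()
        if x.size == 0:
            return {c: np.nan for c in ("mean_rs", "sd", "median", "p25", "p75", "min", "max")} | {"n": 0}
        return {
            "mean_rs": float(x.mean()),
            "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
            "median": float(np.median(x)),
            "p25": float(np.percentile(x, 25)),
            "p75": float(np.percentile(x, 75)),
            "min": float(x.min()),
            "max": float(x.max()),
            "n": int(x.size),
        }

    out = {m: row(indices[m]) for m in indices.columns}
    pooled = pd.concat([indices[m] for m in indices.columns], ignore_index=True)
    out["pooled"] = row(pooled)
    summary = pd.DataFrame(out).T
    summary["n"] = summary["n"].astype(int)
    return summary


def stability_analysis(
    source: CohortTable | AssociationMatrix,
    B: int = DEFAULT_B,
    scheme: str = "matrix_nodes",
    threshold: float = 0.2,
    seed: int | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, BootstrapResult]:
    """End-to-end stability run: bootstrap, index, summarize.

    Returns (summary table, per-replicate index table, raw bootstrap
    result).
    """
    boot = bootstrap_centrality(source, B, scheme, threshold, seed, **kwargs)
    rows = [
        {m: stability_index(boot.original[m], rep[m]) for m in MEASURES}
        for rep in boot.replicates
    ]
    indices = pd.DataFrame(rows, columns=list(MEASURES))
    return summarize_stability(indices), indices, boot
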