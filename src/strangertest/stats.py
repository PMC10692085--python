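"""Expert-score aggregation, inter-rater agreement, and cluster validation.

Three experts score each trial on an ordinal -2..+2 scale; scores are
collapsed by sign to three classes ('-', '0', '+') and aggregated by
majority vote (three-way ties are flagged, never imputed).  Agreement is
quantified by the Fleiss-style pairwise percent agreement Po and
Randolph's free-marginal multirater kappa,

    kappa = (Po - 1/c) / (1 - 1/c),   c = number of categories,

appropriate when raters are not constrained to fixed category
frequencies.  Cluster validity against the C-BARQ is assessed with a
two-sided Mann-Whitney U test per category (min-side U, tie-corrected
normal approximation; exact enumeration for small samples).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

CLASSES = ("-", "0", "+")
CBARQ_CATEGORIES = ("SDA", "ODA", "SDF", "NSF", "SRB", "ASB", "EXC", "PS")

#: raw-score sign collapse: -2,-1 -> '-';  0 -> '0';  +1,+2 -> '+'
_VALID_RAW = {-2, -1, 0, 1, 2}


def collapse_score(raw: int) -> str:
    """Collapse a raw -2..+2 score to its sign class."""
    if raw not in _VALID_RAW:
        raise ValueError(f"raw score {raw!r} outside {{-2..+2}}")
    return "-" if raw < 0 else ("+" if raw > 0 else "0")


def collapse_and_vote(raw_scores) -> tuple[tuple[str, str, str], str | None]:
    """Sign-collapse three raw scores and majority-vote the final label.

    Returns ``(collapsed, label)``; ``label`` is None on a three-way tie.
    Accepts raw integers in -2..+2 or already-collapsed symbols.
    Invariant under rater permutation.
    """
    if len(raw_scores) != 3:
        raise ValueError("exactly three raters are required")
    collapsed = tuple(
        s if isinstance(s, str) and s in CLASSES else collapse_score(int(s))
        for s in raw_scores
    )
    counts = {c: collapsed.count(c) for c in set(collapsed)}
    top, votes = max(counts.items(), key=lambda kv: kv[1])
    return collapsed, (top if votes >= 2 else None)


def majority_labels(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-trial collapsed classes and majority label (NaN on ties).

    ``ratings`` columns: trial_id, rater1, rater2, rater3.
    """
    rows = []
    for _, r in ratings.iterrows():
        collapsed, label = collapse_and_vote((r["rater1"], r["rater2"], r["rater3"]))
        rows.append({"trial_id": r["trial_id"],
                     "rater1": collapsed[0], "rater2": collapsed[1],
                     "rater3": collapsed[2], "label": label})
    return pd.DataFrame(rows)


def percent_agreement(matrix) -> float:
    """Fleiss observed pairwise agreement Po.

    ``matrix``: (n_subjects, n_raters) of category labels, no missing
    entries.  Po = mean over subjects of (agreeing rater pairs) /
    (total pairs).  Invariant under category relabeling.
    """
    M = np.asarray(matrix, dtype=object)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ValueError("need a complete subjects x raters matrix with >= 2 raters")
    if pd.DataFrame(M).isna().to_numpy().any():
        raise ValueError("rating matrix has missing entries")
    n_raters = M.shape[1]
    total_pairs = comb(n_raters, 2)
    per_subject = []
    for row in M:
        agree = sum(1 for a, b in itertools.combinations(row, 2) if a == b)
        per_subject.append(agree / total_pairs)
    return float(np.mean(per_subject))


def free_marginal_kappa(po: float, n_categories: int = 3) -> float:
    """Randolph's free-marginal multirater kappa from observed agreement."""
    if not 0 <= po <= 1:
        raise ValueError("Po must lie in [0, 1]")
    if n_categories < 2:
        raise ValueError("need at least 2 categories")
    pe = 1.0 / n_categories
    return (po - pe) / (1.0 - pe)


@dataclass
class AgreementReport:
    n_subjects: int
    percent_agreement: float
    kappa: float
    n_categories: int = 3


def agreement_report(matrix, n_categories: int = 3) -> AgreementReport:
    po = percent_agreement(matrix)
    return AgreementReport(
        n_subjects=len(np.asarray(matrix, dtype=object)),
        percent_agreement=po,
        kappa=free_marginal_kappa(po, n_categories),
        n_categories=n_categories,
    )


@dataclass
class MannWhitneyResult:
    U: float                 # min-side statistic
    z: float                 # tie-corrected normal approximation
    p: float                 # two-sided
    median_x: float
    median_y: float
    n_x: int
    n_y: int
    p_exact: float | None = None


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x against y, with midrank tie handling."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def mann_whitney(x, y, exact_limit: int = 12) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Reports the min-side U, a tie- and continuity-corrected z, and the
    two-sided normal-approximation p.  For pooled
    samples of at most ``exact_limit`` observations the exact two-sided
    p (full enumeration of group labelings, ties included) is also
    computed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    u1 = _u_statistic(x, y)
    u2 = n1 * n2 - u1
    u = min(u1, u2)

    pooled = np.concatenate([x, y])
    N = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum() / (N * (N - 1))) if N > 1 else 0.0
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    mean_u = n1 * n2 / 2.0
    if var <= 0:  # all observations tied
        z, p = 0.0, 1.0
    else:
        # continuity-corrected z on the min side (u <= mean_u)
        z = (u - mean_u + 0.5) / np.sqrt(var)
        p = min(2.0 * norm.cdf(z), 1.0)
        p = max(p, np.finfo(float).tiny)

    p_exact = None
    if N <= exact_limit:
        count = 0
        total = comb(N, n1)
        for idx in itertools.combinations(range(N), n1):
            xs = pooled[list(idx)]
            ys = np.delete(pooled, list(idx))
            u_perm = _u_statistic(xs, ys)
            if min(u_perm, n1 * n2 - u_perm) <= u + 1e-9:
                count += 1
        p_exact = count / total

    return MannWhitneyResult(
        U=u, z=float(z), p=float(p),
        median_x=float(np.median(x)), median_y=float(np.median(y)),
        n_x=n1, n_y=n2, p_exact=p_exact,
    )


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(running, 1.0)
    return adj


def compare_clusters_cbarq(
    profiles: pd.DataFrame, assignments: dict[str, int]
) -> pd.DataFrame:
    """Mann-Whitney per C-BARQ category between the two clusters.

    ``profiles`` columns: trial_id plus the 8 categories.  Returns one
    row per category with per-cluster medians, U, z and the raw
    two-sided p (no correction, matching the single-category reporting
    convention); a Holm-adjusted column is added as a labeled extension.
    """
    clusters = sorted(set(assignments.values()))
    if len(clusters) != 2:
        raise ValueError(f"pairwise design requires exactly 2 clusters, got {len(clusters)}")
    prof = profiles.set_index("trial_id")
    ids = [t for t in prof.index if t in assignments]
    g0 = [t for t in ids if assignments[t] == clusters[0]]
    g1 = [t for t in ids if assignments[t] == clusters[1]]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each cluster needs at least 2 trials")
    rows = []
    for cat in CBARQ_CATEGORIES:
        res = mann_whitney(prof.loc[g0, cat], prof.loc[g1, cat])
        rows.append({"category": cat,
                     f"median_cluster{clusters[0]}": res.median_x,
                     f"median_cluster{clusters[1]}": res.median_y,
                     "U": res.U, "z": res.z, "p": res.p})
    out = pd.DataFrame(rows)
    out["p_holm_extension"] = _holm(out["p"].to_numpy())
    return out
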