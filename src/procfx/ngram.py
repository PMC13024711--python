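"""N-gram chi-square feature selection with TF-ISF weighting.

Unigrams and bigrams of encoded action tokens are ranked by the chi-square
of a 2x2 contingency table whose rows are *this n-gram* vs *all other
n-grams of the same order* and whose columns are *successful* vs *failed*
sequences.  Cells hold TF-ISF mass rather than raw counts:

    tfisf(tf, N, sf) = (1 + log tf) * log(N / sf)    for tf >= 1, else 0

with ``tf`` the within-sequence count, ``N`` the corpus size and ``sf`` the
number of sequences containing the n-gram, summed over the sequences of
each outcome group.  The weighting down-ranks n-grams that occur in nearly
every sequence and makes the statistic robust to length variation.
P-values come from the chi-square distribution with one degree of freedom
(no continuity correction) and are corrected per representation by the
Benjamini-Hochberg step-up procedure; survivors are the *key action
segments*.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .effectiveness import EncodedSequence

__all__ = [
    "extract_ngrams",
    "tfisf_weight",
    "chisq_phi",
    "bh_adjust",
    "select_key_segments",
    "segment_summary",
]


def _token_lists(corpus: Iterable) -> list[list]:
    out = []
    for seq in corpus:
        out.append(list(seq.tokens) if isinstance(seq, EncodedSequence) else list(seq))
    return out


def extract_ngrams(corpus: Sequence, n: int) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sequence n-gram counts and sequence frequencies.

    Returns ``(tf, sf)`` where ``tf`` is an (n-gram x sequence) count frame
    and ``sf[g] = number of sequences containing g``.  Bigrams are pairs of
    consecutive tokens within a sequence (actor changes do not break
    adjacency); sequences shorter than ``n`` contribute nothing.
    """
    if n not in (1, 2):
        raise ValueError(f"n must be 1 or 2, got {n}")
    seqs = _token_lists(corpus)
    if not seqs:
        raise ValueError("empty corpus")
    counts: dict[tuple, np.ndarray] = {}
    m = len(seqs)
    for j, tokens in enumerate(seqs):
        for i in range(len(tokens) - n + 1):
            g = tuple(tokens[i : i + n])
            row = counts.get(g)
            if row is None:
                row = counts[g] = np.zeros(m, dtype=np.int64)
            row[j] += 1
    tf = pd.DataFrame.from_dict(counts, orient="index")
    tf.index.name = "ngram"
    sf = (tf > 0).sum(axis=1)
    sf.name = "sf"
    return tf, sf


def tfisf_weight(tf, N: int, sf, base: float = math.e):
    """TF-ISF weight; 0 where ``tf == 0``, else ``(1 + log tf) * log(N / sf)``."""
    if N < 1:
        raise ValueError("N must be >= 1")
    tf = np.asarray(tf, dtype=float)
    sf = np.asarray(sf, dtype=float)
    if np.any((tf >= 1) & (sf == 0)):
        raise ValueError("inconsistent counts: tf >= 1 with sf == 0")
    lb = math.log(base)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (1.0 + np.log(np.maximum(tf, 1.0)) / lb) * (np.log(N / np.maximum(sf, 1.0)) / lb)
    w = np.where(tf == 0, 0.0, w)
    return float(w) if w.ndim == 0 else w


def chisq_phi(table) -> tuple[float, float, float, int]:
    """Chi-square, phi, p and direction for a 2x2 table of non-negative masses.

    ``chi2 = sum (O - E)^2 / E`` with expectations from the margins, df = 1,
    no continuity correction; ``phi = sqrt(chi2 / T)`` with T the grand
    total; ``direction = sign(O[0,0] - E[0,0])`` (+1 when the first-row
    entity is overrepresented in the first column).
    """
    O = np.asarray(table, dtype=float)
    if O.shape != (2, 2) or (O < 0).any():
        raise ValueError("table must be 2x2 with non-negative entries")
    rows, cols = O.sum(axis=1), O.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin in contingency table")
    T = O.sum()
    E = np.outer(rows, cols) / T
    chi2 = float(((O - E) ** 2 / E).sum())
    phi = math.sqrt(chi2 / T)
    p = float(scipy.stats.chi2.sf(chi2, df=1))
    direction = int(np.sign(O[0, 0] - E[0, 0]))
    return chi2, phi, p, direction


def bh_adjust(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment: ``(p_adj, reject)``."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def select_key_segments(
    corpus: Sequence,
    outcome_labels: Sequence[bool],
    n: int,
    alpha: float = 0.05,
    log_base: float = math.e,
) -> pd.DataFrame:
    """Rank all n-grams of one representation by TF-ISF chi-square.

    ``outcome_labels[j]`` is True when sequence ``j`` completed the task.
    For each n-gram the 2x2 table is::

                      success      failure
        this n-gram   sum tfisf    sum tfisf
        all others    rest mass    rest mass

    summed over the sequences of each group; n-grams with a zero margin are
    skipped with a warning.  Returns one row per n-gram with columns
    (ngram, n, tf_total, sf, chi2, phi, p, p_adj, direction, key), sorted
    by chi2 descending (ties broken lexicographically).
    """
    labels = np.asarray(outcome_labels, dtype=bool)
    seqs = _token_lists(corpus)
    if len(labels) != len(seqs):
        raise ValueError("outcome_labels and corpus length mismatch")
    if labels.all() or not labels.any():
        raise ValueError("degenerate corpus: need both successful and failed sequences")
    tf, sf = extract_ngrams(seqs, n)
    N = len(seqs)
    W = tfisf_weight(tf.to_numpy(), N, sf.to_numpy()[:, None], base=log_base)
    mass_s = W[:, labels].sum(axis=1)
    mass_f = W[:, ~labels].sum(axis=1)
    tot_s, tot_f = mass_s.sum(), mass_f.sum()

    records = []
    for i, g in enumerate(tf.index):
        table = np.array(
            [[mass_s[i], mass_f[i]], [tot_s - mass_s[i], tot_f - mass_f[i]]]
        )
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            warnings.warn(f"n-gram {g!r} skipped: zero margin in its contingency table")
            continue
        chi2, phi, p, direction = chisq_phi(table)
        records.append(
            {
                "ngram": g,
                "n": n,
                "tf_total": int(tf.iloc[i].sum()),
                "sf": int(sf.iloc[i]),
                "chi2": chi2,
                "phi": phi,
                "p": p,
                "direction": direction,
            }
        )
    df = pd.DataFrame.from_records(records)
    if df.empty:
        return df.assign(p_adj=[], key=[])
    p_adj, reject = bh_adjust(df["p"].to_numpy(), alpha=alpha)
    df["p_adj"] = p_adj
    df["key"] = reject
    df["_tiebreak"] = df["ngram"].map(lambda g: tuple(str(t) for t in g))
    df = df.sort_values(["chi2", "_tiebreak"], ascending=[False, True], kind="mergesort")
    return df.drop(columns="_tiebreak").reset_index(drop=True)


def segment_summary(df: pd.DataFrame) -> dict:
    """Counts and mean chi2/phi for total and key segments (one representation/order)."""
    key = df[df["key"]] if "key" in df else df.iloc[0:0]
    return {
        "total_count": int(len(df)),
        "total_mean_chi2": float(df["chi2"].mean()) if len(df) else math.nan,
        "total_mean_phi": float(df["phi"].mean()) if len(df) else math.nan,
        "key_count": int(len(key)),
        "key_mean_chi2": float(key["chi2"].mean()) if len(key) else math.nan,
        "key_mean_phi": float(key["phi"].mean()) if len(key) else math.nan,
        "key_proportion": float(len(key) / len(df)) if len(df) else math.nan,
    }
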