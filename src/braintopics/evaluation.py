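"""Decoder evaluation: annotation ranks, permutation nulls, recovery metrics.

The headline check for an image-to-text decoder: decode each image, rank a
fixed candidate term list by the decoded weights, locate each human (or
ground-truth) annotation in that ranking, and compare the median annotation
rank against a null distribution obtained by permuting the image-annotation
pairing across images.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import rankdata

from .model import ModelState, estimate_phi, lateralization


def term_ranks(word_weights, candidate_terms, annotations, vocabulary):
    """Rank each annotation within the weight-sorted candidate list.

    Candidates are sorted by descending decoded weight with average ranks on
    ties (rank 1 = highest weight).  Annotations absent from the candidate
    list are reported with rank NaN (missing), not ranked.  Returns a
    ``pandas.Series`` indexed by annotation.
    """
    if len(candidate_terms) == 0:
        raise ValueError("candidate term list is empty")
    word_weights = np.asarray(word_weights, dtype=float)
    vocab_index = {w: i for i, w in enumerate(vocabulary)}
    missing_vocab = [t for t in candidate_terms if t not in vocab_index]
    if missing_vocab:
        raise ValueError(f"candidate terms not in vocabulary: {missing_vocab[:5]}")
    weights = word_weights[[vocab_index[t] for t in candidate_terms]]
    ranks = rankdata(-weights, method="average")
    by_term = dict(zip(candidate_terms, ranks))
    return pd.Series(
        {t: by_term.get(t, math.nan) for t in annotations}, dtype=float, name="rank"
    )


def candidate_rank_matrix(weight_matrix):
    """Per-image average ranks (1 = best) of every candidate term.

    ``weight_matrix`` is (n_images, n_candidates) of decoded weights; the
    result has the same shape.
    """
    w = np.asarray(weight_matrix, dtype=float)
    return np.vstack([rankdata(-row, method="average") for row in w])


def pairing_statistic(rank_matrix, annotation_indices, statistic=np.median):
    """The statistic (default median) over all (image, annotation) ranks."""
    vals = [rank_matrix[i, j] for i, idx in enumerate(annotation_indices) for j in idx]
    if not vals:
        raise ValueError("no annotations to score")
    return float(statistic(np.asarray(vals)))


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float


def permutation_null(
    rank_matrix,
    annotation_indices,
    n_perm: int = 1000,
    seed: int = 0,
    statistic=np.median,
    exhaustive: bool = False,
) -> PermutationResult:
    """Permutation null for the annotation-rank statistic.

    Each permutation shuffles the image-annotation pairing across images
    (image i is scored against the annotations of a permuted image),
    recomputes every annotation's rank, and records the statistic over all
    annotations.  Lower ranks are better, so the empirical p-value is
    p = (1 + #{null <= observed}) / (1 + n_perm), with +1 smoothing.

    ``rank_matrix`` is (n_images, n_candidates) as from
    :func:`candidate_rank_matrix`; ``annotation_indices`` gives each image's
    annotations as candidate-column indices.  With ``exhaustive=True`` all
    n! pairings are enumerated instead of sampled (small n only).
    """
    rank_matrix = np.asarray(rank_matrix, dtype=float)
    n_images = rank_matrix.shape[0]
    if n_images < 2:
        raise ValueError("need at least 2 images")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = pairing_statistic(rank_matrix, annotation_indices, statistic)

    def permuted_stat(perm):
        return pairing_statistic(
            rank_matrix, [annotation_indices[perm[i]] for i in range(n_images)], statistic
        )

    if exhaustive:
        null = np.array([permuted_stat(p) for p in itertools.permutations(range(n_images))])
    else:
        rng = np.random.default_rng(seed)
        null = np.array([permuted_stat(rng.permutation(n_images)) for _ in range(n_perm)])
    p = (1 + int((null <= observed).sum())) / (1 + len(null))
    return PermutationResult(observed=observed, null=null, p_value=p)


def recovery_report(truth, fitted: ModelState) -> pd.DataFrame:
    """Match fitted topics to ground-truth topics and score the recovery.

    Topics are matched one-to-one (Hungarian assignment) on the mean
    distance between corresponding subregion means.  The report gives, per
    true topic: the matched fitted topic, the mean spatial-mean error (mm),
    the cosine similarity of the word distributions, and — for symmetric
    models — the true/fitted lateralization coefficients and their absolute
    error.
    """
    T = truth.spatial.n_topics
    if fitted.params.n_topics != T:
        raise ValueError("topic count mismatch between truth and fitted model")
    mu_true = truth.spatial.mu  # (T, R, 3)
    mu_fit = fitted.spatial.mu
    if mu_true.shape != mu_fit.shape:
        raise ValueError("subregion count mismatch between truth and fitted model")
    # pairwise cost: mean over subregions of the Euclidean mean distance
    dists = np.linalg.norm(mu_true[:, None] - mu_fit[None, :], axis=-1)  # (T, T, R)
    cost = dists.mean(axis=-1)
    rows_t, cols_f = linear_sum_assignment(cost)

    phi_true = truth.phi.phi if hasattr(truth.phi, "phi") else np.asarray(truth.phi)
    phi_fit = estimate_phi(fitted).phi
    symmetric = fitted.params.symmetric
    lat_true = lateralization(truth.spatial) if symmetric else None
    lat_fit = lateralization(fitted) if symmetric else None

    records = []
    for t, f in zip(rows_t, cols_f):
        u, v = phi_true[:, t], phi_fit[:, f]
        cos = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
        rec = {
            "true_topic": int(t),
            "fitted_topic": int(f),
            "mu_error_mm": float(cost[t, f]),
            "word_cosine": cos,
        }
        if symmetric:
            rec["lat_true"] = float(lat_true[t])
            rec["lat_fitted"] = float(lat_fit[f])
            rec["lat_error"] = abs(rec["lat_true"] - rec["lat_fitted"])
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("true_topic").sort_index()
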