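"""Cross-validated top-k feature selection by JT p-value ranking.

This is the outer layer of a two-layer scheme for building predictive
models on high-dimensional ordinal features: for each training
partition, every feature is JT-tested against every trait, features are
ranked by ascending p-value, and the top k are handed to whatever model
the user fits downstream.  Held-out samples never contribute to their
own fold's ranking, so selection is honestly cross-validated.

Ranking is fully deterministic: ties on p break by |Z| descending, then
by input feature order; invalid tests (degenerate groups, zero
variance) rank last in input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .kernel import OpCounter, Status
from .scan import OrdinalFeatureMatrix, TraitMatrix, scan

__all__ = [
    "FoldAssignment",
    "CVSelectionReport",
    "make_folds",
    "rank_features",
    "select_top_k",
    "cv_select",
    "loo_select",
]


@dataclass
class FoldAssignment:
    """Deterministic k-fold partition: a pure function of (n, k, seed)."""

    fold_of_sample: np.ndarray
    k: int
    seed: int

    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.fold_of_sample, minlength=self.k)


@dataclass
class CVSelectionReport:
    """Per-fold top-k selections plus cross-fold selection frequencies.

    ``selections`` has columns (fold, trait_id, rank, feature_id, p);
    ``selection_frequency`` has columns (trait_id, feature_id, frequency)
    where frequency is the fraction of folds that selected the feature
    for that trait.
    """

    selections: pd.DataFrame
    selection_frequency: pd.DataFrame
    top_n: int
    k: int
    seed: Optional[int] = None


def make_folds(n: int, k: int, seed: int) -> FoldAssignment:
    """Seeded uniform shuffle, then contiguous blocks of near-equal size.

    The first ``n mod k`` folds get ``ceil(n/k)`` samples, the rest
    ``floor(n/k)``; fold sizes differ by at most one.
    """
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    base, extra = divmod(n, k)
    fold_of_sample = np.empty(n, dtype=np.int64)
    start = 0
    for f in range(k):
        size = base + (1 if f < extra else 0)
        fold_of_sample[perm[start : start + size]] = f
        start += size
    return FoldAssignment(fold_of_sample=fold_of_sample, k=k, seed=seed)


def _rank_order(sub: pd.DataFrame) -> np.ndarray:
    """Deterministic ranking key over one trait's scan rows.

    Valid rows first by (p ascending, |Z| descending, input order);
    invalid rows last, in input order.
    """
    invalid = (sub["status"] != Status.OK.value).to_numpy()
    p = sub["p"].to_numpy(dtype=float)
    absz = np.abs(sub["Z"].to_numpy(dtype=float))
    p = np.where(invalid | ~np.isfinite(p), np.inf, p)
    absz = np.where(invalid | ~np.isfinite(absz), -np.inf, absz)
    order_in = np.arange(len(sub))
    # lexsort: last key is primary
    return np.lexsort((order_in, -absz, p, invalid.astype(int)))


def rank_features(results: pd.DataFrame, trait_id) -> list:
    """Feature IDs for one trait, ordered by ascending JT p-value."""
    sub = results[results["trait_id"] == trait_id].reset_index(drop=True)
    if sub.empty:
        raise KeyError(f"trait {trait_id!r} not present in results")
    order = _rank_order(sub)
    return [sub["feature_id"].iloc[i] for i in order]


def select_top_k(results: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k features per trait; columns (trait_id, rank, feature_id, p).

    Only valid (status OK) features are eligible; if fewer than k are
    valid, all valid features are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rows = []
    for trait_id in pd.unique(results["trait_id"]):
        sub = results[results["trait_id"] == trait_id].reset_index(drop=True)
        order = _rank_order(sub)
        valid = sub["status"].to_numpy() == Status.OK.value
        picked = [i for i in order if valid[i]][:k]
        for rank, i in enumerate(picked, start=1):
            rows.append(
                {
                    "trait_id": trait_id,
                    "rank": rank,
                    "feature_id": sub["feature_id"].iloc[i],
                    "p": sub["p"].iloc[i],
                }
            )
    return pd.DataFrame(rows, columns=["trait_id", "rank", "feature_id", "p"])


def _cv_from_assignment(
    features: OrdinalFeatureMatrix,
    traits: TraitMatrix,
    folds: FoldAssignment,
    top_n: int,
    threads: int,
    sided: str,
    counter: Optional[OpCounter],
) -> CVSelectionReport:
    all_rows = []
    for f in range(folds.k):
        train = np.nonzero(folds.fold_of_sample != f)[0]
        res = scan(
            features.subset_samples(train),
            traits.subset_samples(train),
            threads=threads,
            sided=sided,
            counter=counter,
        )
        sel = select_top_k(res, top_n)
        sel.insert(0, "fold", f)
        all_rows.append(sel)
    selections = pd.concat(all_rows, ignore_index=True)
    freq = (
        selections.groupby(["trait_id", "feature_id"], sort=True)
        .size()
        .div(folds.k)
        .rename("frequency")
        .reset_index()
    )
    return CVSelectionReport(
        selections=selections,
        selection_frequency=freq,
        top_n=top_n,
        k=folds.k,
        seed=folds.seed,
    )


def cv_select(
    features: OrdinalFeatureMatrix,
    traits: TraitMatrix,
    k: int,
    top_n: int = 10,
    seed: int = 0,
    threads: int = 1,
    sided: str = "two",
    counter: Optional[OpCounter] = None,
) -> CVSelectionReport:
    """k-fold cross-validated top-k selection.

    For each fold, the scan runs on the training samples only (those not
    in the fold) and the top ``top_n`` features per trait are recorded.
    Identical (data, k, top_n, seed) always yield an identical report.
    """
    folds = make_folds(features.n_samples, k, seed)
    return _cv_from_assignment(
        features, traits, folds, top_n, threads, sided, counter
    )


def loo_select(
    features: OrdinalFeatureMatrix,
    traits: TraitMatrix,
    top_n: int = 10,
    threads: int = 1,
    sided: str = "two",
    counter: Optional[OpCounter] = None,
) -> CVSelectionReport:
    """Leave-one-out selection: fold i holds out exactly sample i.

    The report's ``selections`` carry a ``held_out_sample`` column: the
    features chosen for that fold were selected without any use of that
    sample — the hand-off point for an external per-sample model fit.
    """
    n = features.n_samples
    if n < 2:
        raise ValueError("leave-one-out requires at least 2 samples")
    folds = FoldAssignment(
        fold_of_sample=np.arange(n, dtype=np.int64), k=n, seed=0
    )
    report = _cv_from_assignment(
        features, traits, folds, top_n, threads, sided, counter
    )
    report.selections.insert(
        1,
        "held_out_sample",
        [features.sample_ids[f] for f in report.selections["fold"]],
    )
    return report


def write_selection_report(report: CVSelectionReport, path, freq_path=None) -> None:
    """Serialize selections (and optionally frequencies) as TSV."""
    report.selections.to_csv(path, sep="\t", index=False)
    if freq_path is not None:
        report.selection_frequency.to_csv(freq_path, sep="\t", index=False)
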