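"""Assessment statistics: per-protein AUC, wAUC, mAUC, tAUC, funnel, counts.

Binding-site prediction only needs to rank residues within one protein, so
accuracy is assessed per protein by the ROC AUC and aggregated over a
dataset either as the length-weighted mean (wAUC) or the plain mean
(mAUC). The conventional pooled AUC over all residues of all proteins
(tAUC) is kept as a reference; it rewards cross-protein comparisons that
the prediction task never requires.

Also here: the energy-funnel correlation (prediction score against the
minimum residue-to-NA distance near the interface) and the sequence-
composition estimator of the binding-site count from the six residue
types Arg, Asp, Gly, His, Lys, Thr.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

SIX_RESIDUE_TYPES = frozenset("RDGHKT")


class UndefinedAUCError(ValueError):
    """Raised when labels contain only one class."""


def auc_single(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC of one protein via the tie-aware (midrank) rank statistic.

    AUC = P(score_pos > score_neg) + 1/2 P(tie); identical to the
    trapezoidal ROC area. Requires at least one positive and one negative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError(f"AUC undefined: {n_pos} positives, {n_neg} negatives")
    ranks = stats.rankdata(scores)  # midranks
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def wauc(aucs, lengths) -> float:
    """Length-weighted mean AUC: sum AUC(i) x len(i) / sum len(i)."""
    aucs = np.asarray(aucs, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if aucs.size == 0 or aucs.shape != lengths.shape:
        raise ValueError("need equal-length, non-empty AUC and length lists")
    if np.any(lengths <= 0):
        raise ValueError("protein lengths must be positive")
    return float((aucs * lengths).sum() / lengths.sum())


def mauc(aucs) -> float:
    """Unweighted mean AUC over proteins."""
    aucs = np.asarray(aucs, dtype=float)
    if aucs.size == 0:
        raise ValueError("need at least one AUC")
    return float(aucs.mean())


def tauc(score_lists, label_lists) -> float:
    """Pooled ("total") AUC over all residues of all proteins together."""
    scores = np.concatenate([np.asarray(s, dtype=float) for s in score_lists])
    labels = np.concatenate([np.asarray(l, dtype=bool) for l in label_lists])
    return auc_single(scores, labels)


@dataclass
class EvaluationReport:
    """Per-protein AUCs and the three dataset aggregates at one cutoff."""

    names: list[str]
    aucs: list[float]
    lengths: list[int]
    n_binding: list[int]
    wauc: float
    mauc: float
    tauc: float
    cutoff: float
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["protein\tlength\tn_binding\tauc"]
        for name, ln, nb, a in zip(self.names, self.lengths, self.n_binding, self.aucs):
            lines.append(f"{name}\t{ln}\t{nb}\t{a:.6f}")
        lines.append(f"# cutoff_A\t{self.cutoff}")
        lines.append(f"# wAUC\t{self.wauc:.6f}")
        lines.append(f"# mAUC\t{self.mauc:.6f}")
        lines.append(f"# tAUC\t{self.tauc:.6f}")
        for name, why in self.skipped:
            lines.append(f"# skipped\t{name}\t{why}")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "wauc": self.wauc, "mauc": self.mauc, "tauc": self.tauc,
            "proteins": [
                {"name": n, "length": ln, "n_binding": nb, "auc": a}
                for n, ln, nb, a in zip(self.names, self.lengths, self.n_binding, self.aucs)
            ],
            "skipped": [{"name": n, "reason": r} for n, r in self.skipped],
        }


def evaluate_dataset(entries, cutoff: float = 3.5) -> EvaluationReport:
    """Aggregate AUCs over (name, scores, labels) triples.

    Proteins whose labels are single-class at this cutoff have no defined
    AUC; they are skipped (and logged in the report) for wAUC/mAUC, while
    tAUC pools every residue regardless.
    """
    names, aucs, lengths, n_binding = [], [], [], []
    pooled_scores, pooled_labels, skipped = [], [], []
    for name, scores, labels in entries:
        labels = np.asarray(labels, dtype=bool)
        pooled_scores.append(scores)
        pooled_labels.append(labels)
        try:
            a = auc_single(scores, labels)
        except UndefinedAUCError as exc:
            skipped.append((name, str(exc)))
            continue
        names.append(name)
        aucs.append(a)
        lengths.append(len(labels))
        n_binding.append(int(labels.sum()))
    if not aucs:
        raise UndefinedAUCError(f"no evaluable protein at cutoff {cutoff}")
    return EvaluationReport(
        names=names, aucs=aucs, lengths=lengths, n_binding=n_binding,
        wauc=wauc(aucs, lengths), mauc=mauc(aucs),
        tauc=tauc(pooled_scores, pooled_labels), cutoff=cutoff, skipped=skipped,
    )


@dataclass
class FunnelProfile:
    """Score-vs-distance pairs near the interface and their Pearson r."""

    min_distances: np.ndarray
    scores: np.ndarray
    mask: np.ndarray
    pearson_r: float
    region_limit: float

    def to_tsv(self) -> str:
        lines = ["min_dist_A\te_pred"]
        for d, s in zip(self.min_distances[self.mask], self.scores[self.mask]):
            lines.append(f"{d:.3f}\t{s:.6f}")
        lines.append(f"# pearson_r\t{self.pearson_r:.6f}")
        return "\n".join(lines) + "\n"


def funnel_correlation(min_distances: np.ndarray, scores: np.ndarray,
                       region_limit: float = 20.0) -> FunnelProfile:
    """Pearson correlation between prediction score and residue-NA distance.

    Only residues within ``region_limit`` Angstrom of the NA ("around the
    binding region") enter the correlation. The signed r is reported; a
    working predictor scores interface residues high, so r is negative
    under this orientation, and callers interested in funnel strength
    should look at |r|.
    """
    min_distances = np.asarray(min_distances, dtype=float)
    scores = np.asarray(scores, dtype=float)
    mask = min_distances <= region_limit
    if mask.sum() < 3:
        raise ValueError(f"fewer than 3 residues within {region_limit} Angstrom of NA")
    x = min_distances[mask]
    y = scores[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("funnel correlation undefined: zero variance")
    r = float(stats.pearsonr(x, y).statistic)
    return FunnelProfile(min_distances=min_distances, scores=scores, mask=mask,
                         pearson_r=r, region_limit=region_limit)


def six_type_fraction(sequence: str) -> float:
    """Fraction of the sequence in {Arg, Asp, Gly, His, Lys, Thr}."""
    if not sequence:
        raise ValueError("empty sequence")
    return sum(1 for c in sequence.upper() if c in SIX_RESIDUE_TYPES) / len(sequence)


@dataclass
class CountEstimator:
    """Linear map from six-residue-type fraction to binding-residue fraction."""

    slope: float
    intercept: float
    pearson_r: float

    def estimate_binding_count(self, sequence: str) -> int:
        """Predicted number of NA-binding residues, floored at 0 and rounded."""
        frac = self.slope * six_type_fraction(sequence) + self.intercept
        return int(round(max(0.0, frac) * len(sequence)))


def fit_count_estimator(sequences: list[str], n_binding: list[int]) -> CountEstimator:
    """Least-squares fit of binding fraction on six-type composition fraction.

    Fractions rather than raw counts are regressed so that protein length
    does not dominate the fit; the count estimate is the fitted fraction
    times sequence length.
    """
    if len(sequences) < 3 or len(sequences) != len(n_binding):
        raise ValueError("need at least 3 (sequence, count) pairs")
    x = np.array([six_type_fraction(s) for s in sequences])
    y = np.array([nb / len(s) for s, nb in zip(sequences, n_binding)], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all proteins share one composition fraction")
    fit = stats.linregress(x, y)
    return CountEstimator(slope=float(fit.slope), intercept=float(fit.intercept),
                          pearson_r=float(fit.rvalue))
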