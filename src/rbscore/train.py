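"""Fitting the 104 weights: simulated-annealing Monte Carlo on wAUC.

wAUC is piecewise constant in the weights (it only depends on residue
rankings), so gradient methods do not apply; the trainer instead perturbs
one randomly chosen parameter at a time with Gaussian noise and accepts
uphill moves always and downhill moves with the Metropolis probability
exp(dwAUC / T) under a geometric cooling schedule. The non-negativity of
w_CE and w_width is kept by reflecting proposals at zero. Protein-level
5-fold cross-validation selects the best model by validation wAUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from rbscore.evaluate import UndefinedAUCError, auc_single, wauc
from rbscore.params import ParameterVector
from rbscore.pipeline import FeaturizedProtein
from rbscore.scoring import compile_edges, e_pred_from_edges, _type_indices

# flat-vector indices whose values must stay non-negative (w_CE, w_width)
_NONNEG_IDX = (30, 31)


@dataclass
class TrainingConfig:
    """Simulated-annealing schedule and cross-validation settings.

    Temperatures are in wAUC units; single-parameter moves shift wAUC by
    ~1e-3, so the default initial temperature is 0.01 (hot enough to cross
    small barriers, cold enough that the annealer is not a pure random
    walk). ``proposal_scales`` optionally fixes the per-parameter Gaussian
    step sizes; by default they are derived from the starting vector (see
    :func:`derive_proposal_scales`).
    """

    n_folds: int = 5
    t_initial: float = 0.01
    cooling: float = 0.92
    steps_per_temp: int = 400
    t_min: float = 1e-4
    plateau_temps: int = 15     # stop after this many temperatures without a new best
    seed: int = 0
    cutoff: float = 3.5         # Angstrom; the labeling cutoff the objective assumes
    proposal_scales: np.ndarray | None = None  # None: derived from the starting vector

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if not (0 < self.cooling < 1):
            raise ValueError("cooling factor must lie in (0, 1)")
        if self.t_initial <= 0 or self.t_min <= 0:
            raise ValueError("temperatures must be positive")
        if self.proposal_scales is not None:
            self.proposal_scales = np.asarray(self.proposal_scales, dtype=float)
            if self.proposal_scales.shape != (104,):
                raise ValueError("proposal_scales must have 104 entries")


# parameter blocks of the flat vector with an absolute step-size floor each;
# w_aa/w_elec multiply features spanning tens of units, so their floors are small
_BLOCK_FLOORS = (
    ((0, 20), 0.005),    # w_aa
    ((20, 30), 0.005),   # electrostatics bin weights
    ((30, 32), 0.05),    # w_CE, w_width
    ((32, 52), 0.2),     # C_aa constants
    ((52, 92), 0.1),     # u_aa, v_aa
    ((92, 104), 0.1),    # f, g
)


def derive_proposal_scales(init: ParameterVector, rel: float = 0.3) -> np.ndarray:
    """Per-parameter Gaussian step sizes proportional to the starting weights.

    The data-driven starting vector already carries the right units per
    block (ASA slopes are tiny because ASA spans tens of Angstrom^2, the
    residue constants are order one), so steps are ``rel`` times the
    larger of the parameter's own magnitude, its block's median magnitude,
    and a small absolute floor per block.
    """
    v = np.abs(init.to_vector())
    scales = np.empty(104)
    for (a, b), floor in _BLOCK_FLOORS:
        med = np.median(v[a:b])
        scales[a:b] = rel * np.maximum(np.maximum(v[a:b], med), floor)
    return scales


class DatasetEvaluator:
    """Caches per-protein arrays so one wAUC evaluation is a few matmuls."""

    def __init__(self, proteins: list[FeaturizedProtein]):
        if not proteins:
            raise ValueError("empty dataset")
        self.proteins = proteins
        self._cache = []
        self.evaluable = []
        for p in proteins:
            labels = np.asarray(p.labels, dtype=bool)
            entry = {
                "t_idx": _type_indices(p.features.res_types),
                "asa": p.features.asa,
                "elec": p.features.elec_counts,
                "ce": p.features.ce,
                "width": p.features.width,
                "edges": compile_edges(p.graph),
                "labels": labels,
                "length": len(labels),
            }
            self._cache.append(entry)
            self.evaluable.append(0 < labels.sum() < labels.size)
        if not any(self.evaluable):
            raise UndefinedAUCError("no protein in the dataset has both label classes")

    def predictions(self, params: ParameterVector) -> list[np.ndarray]:
        out = []
        for c in self._cache:
            ef = (params.w_aa[c["t_idx"]] * c["asa"] + c["elec"] @ params.w_elec
                  + params.w_ce * c["ce"] + params.w_width * c["width"]
                  + params.c_aa[c["t_idx"]])
            ep, _, _ = e_pred_from_edges(ef, c["t_idx"], c["edges"], params)
            out.append(ep)
        return out

    def wauc(self, params: ParameterVector) -> float:
        preds = self.predictions(params)
        aucs, lengths = [], []
        for ok, c, ep in zip(self.evaluable, self._cache, preds):
            if not ok:
                continue
            aucs.append(auc_single(ep, c["labels"]))
            lengths.append(c["length"])
        return wauc(aucs, lengths)


def init_parameters(proteins: list[FeaturizedProtein]) -> ParameterVector:
    """Data-driven starting point for the annealer.

    Feature-block slopes start at the pooled point-biserial correlation of
    each feature column with the binding labels, scaled by the column's
    spread so contributions are commensurate; the network block starts at
    u = v = 0.5, f = g = 1 (neighbors initially reinforce).
    """
    X = np.vstack([p.features.matrix() for p in proteins])
    y = np.concatenate([np.asarray(p.labels, dtype=float) for p in proteins])
    pv = ParameterVector()
    if y.std() > 0:
        yc = (y - y.mean()) / y.std()
        for col in range(13):
            x = X[:, col]
            sd = x.std()
            corr = float((yc * (x - x.mean())).mean() / sd) if sd > 0 else 0.0
            w = corr / (sd + 1e-9)
            if col == 0:
                pv.w_aa[:] = w
            elif col <= 10:
                pv.w_elec[col - 1] = w
            elif col == 11:
                pv.w_ce = max(0.0, w)
            else:
                pv.w_width = max(0.0, w)
    pv.u_aa[:] = 0.5
    pv.v_aa[:] = 0.5
    pv.f[:] = 1.0
    pv.g[:] = 1.0
    return pv


def sa_optimize(dataset: list[FeaturizedProtein], init: ParameterVector,
                config: TrainingConfig,
                rng: np.random.Generator | None = None) -> tuple[ParameterVector, list[dict]]:
    """Anneal the parameter vector to maximize training wAUC.

    Returns the best-ever vector and a trace of dicts (step, temperature,
    current and best wAUC), one entry per proposal plus the initial state.
    Fully reproducible from the config seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    evaluator = DatasetEvaluator(dataset)
    scales = (config.proposal_scales if config.proposal_scales is not None
              else derive_proposal_scales(init))

    vec = init.to_vector().copy()
    current = evaluator.wauc(ParameterVector.from_vector(vec))
    best_vec = vec.copy()
    best = current
    trace = [{"step": 0, "temperature": config.t_initial, "wauc": current, "best_wauc": best}]

    temperature = config.t_initial
    step = 0
    temps_since_best = 0
    while temperature >= config.t_min and config.steps_per_temp > 0:
        improved = False
        for _ in range(config.steps_per_temp):
            step += 1
            idx = int(rng.integers(104))
            old = vec[idx]
            vec[idx] = old + rng.normal() * scales[idx]
            if idx in _NONNEG_IDX:
                vec[idx] = abs(vec[idx])  # reflect at zero
            proposal = evaluator.wauc(ParameterVector.from_vector(vec))
            delta = proposal - current
            if delta >= 0 or rng.random() < math.exp(delta / temperature):
                current = proposal
                if current > best:
                    best = current
                    best_vec = vec.copy()
                    improved = True
            else:
                vec[idx] = old
            trace.append({"step": step, "temperature": temperature,
                          "wauc": current, "best_wauc": best})
        temps_since_best = 0 if improved else temps_since_best + 1
        if temps_since_best >= config.plateau_temps:
            break
        temperature *= config.cooling
    return ParameterVector.from_vector(best_vec), trace


@dataclass
class FoldResult:
    fold: int
    train_wauc: float
    validation_wauc: float
    params: ParameterVector


@dataclass
class CVResult:
    folds: list[FoldResult]
    best: FoldResult
    full_refit: ParameterVector | None = None

    @property
    def mean_validation_wauc(self) -> float:
        return float(np.mean([f.validation_wauc for f in self.folds]))

    @property
    def mean_train_wauc(self) -> float:
        return float(np.mean([f.train_wauc for f in self.folds]))


def make_folds(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Disjoint protein-level folds covering range(n), seeded shuffle."""
    order = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(order, n_folds)]


def cross_validate(dataset: list[FeaturizedProtein], config: TrainingConfig,
                   init: ParameterVector | None = None,
                   refit_full: bool = False) -> CVResult:
    """Protein-level k-fold cross-validation of the annealer.

    Every protein lands in exactly one validation fold; each fold's model
    is trained on the remaining proteins only. The selected model is the
    fold with the highest validation wAUC; ``refit_full`` additionally
    retrains on the whole dataset for deployment.
    """
    if len(dataset) < config.n_folds:
        raise ValueError(f"{len(dataset)} proteins but {config.n_folds} folds")
    rng = np.random.default_rng(config.seed)
    folds = make_folds(len(dataset), config.n_folds, rng)
    results: list[FoldResult] = []
    for k, val_idx in enumerate(folds):
        val_set = set(int(i) for i in val_idx)
        train = [p for i, p in enumerate(dataset) if i not in val_set]
        val = [p for i, p in enumerate(dataset) if i in val_set]
        start = init if init is not None else init_parameters(train)
        fold_rng = np.random.default_rng([config.seed, k])
        params, trace = sa_optimize(train, start, config, rng=fold_rng)
        train_w = trace[-1]["best_wauc"]
        val_w = DatasetEvaluator(val).wauc(params)
        results.append(FoldResult(fold=k, train_wauc=train_w,
                                  validation_wauc=val_w, params=params))
    best = max(results, key=lambda r: r.validation_wauc)
    full = None
    if refit_full:
        start = init if init is not None else init_parameters(dataset)
        full, _ = sa_optimize(dataset, start, config,
                              rng=np.random.default_rng([config.seed, config.n_folds]))
    return CVResult(folds=results, best=best, full_refit=full)
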