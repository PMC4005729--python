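"""Ensemble species distribution modelling from presence-only points.

Workflow: deduplicate occurrences per grid cell, screen layers for pairwise
collinearity, draw pseudo-absences (background cells) at a fixed ratio to
presences, fit several base learners on repeated stratified 80/20 splits,
keep members whose held-out AUC exceeds a floor, take the cell-wise median
suitability over the kept members, and binarize it at the threshold that
maximises sensitivity + specificity (Youden's J).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .grids import BinaryRangeMap, EnvStack, OccurrenceSet
from .learners import make_learner


def deduplicate(occ: OccurrenceSet, env: EnvStack) -> OccurrenceSet:
    """Keep at most one occurrence per grid cell (first encountered).

    Points outside the grid are dropped with a warning reporting how many.
    """
    geom = env.geometry
    row, col = geom.cell_of(occ.points[:, 0], occ.points[:, 1])
    inside = geom.inside(row, col)
    n_out = int((~inside).sum())
    if n_out:
        warnings.warn(f"{n_out} point(s) outside the grid were dropped")
    seen = set()
    keep = []
    for i in np.nonzero(inside)[0]:
        cell = (int(row[i]), int(col[i]))
        if cell not in seen:
            seen.add(cell)
            keep.append(i)
    return OccurrenceSet(species=occ.species, points=occ.points[keep],
                         provenance=[occ.provenance[i] for i in keep])


def screen_collinearity(env: EnvStack, priority: list[str] | None = None,
                        r_max: float = 0.7) -> list[str]:
    """Greedy collinearity screen: scan layers in priority order and retain a
    layer iff its |Pearson r| with every already-retained layer is < r_max.

    Constant layers (undefined correlation) are rejected with a warning. The
    retained set depends on the priority order; the scan is deterministic.
    """
    priority = priority if priority is not None else env.layer_names
    rows, cols = np.nonzero(env.mask)
    retained: list[str] = []
    for name in priority:
        vals = env.layers[name][rows, cols]
        if np.std(vals) == 0:
            warnings.warn(f"layer {name!r} is constant over valid cells; rejected")
            continue
        ok = True
        for kept in retained:
            r = np.corrcoef(vals, env.layers[kept][rows, cols])[0, 1]
            if abs(r) >= r_max:
                ok = False
                break
        if ok:
            retained.append(name)
    return retained


def generate_pseudoabsences(occ: OccurrenceSet, env: EnvStack, ratio: int = 10,
                            seed: int = 0) -> OccurrenceSet:
    """Background points: ratio x n_presences cells sampled uniformly without
    replacement from valid cells that hold no presence; points at cell centers."""
    geom = env.geometry
    row, col = geom.cell_of(occ.points[:, 0], occ.points[:, 1])
    presence_cells = set(zip(row.tolist(), col.tolist()))
    rows, cols = np.nonzero(env.mask)
    free = np.array([(r, c) not in presence_cells for r, c in zip(rows, cols)])
    rows, cols = rows[free], cols[free]
    n_needed = ratio * len(occ)
    if n_needed > len(rows):
        raise ValueError(f"need {n_needed} background cells but only {len(rows)} available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n_needed, replace=False)
    x, y = geom.cell_centers(rows[idx], cols[idx])
    return OccurrenceSet(species=occ.species, points=np.column_stack([x, y]),
                         provenance=["pseudo-absence"] * n_needed)


def evaluate_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC in the Mann-Whitney rank form, ties given half credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def sens_spec(scores: np.ndarray, labels: np.ndarray, threshold: float
              ) -> tuple[float, float]:
    """Sensitivity and specificity with the rule: score >= threshold => presence."""
    labels = np.asarray(labels, dtype=int)
    pred = np.asarray(scores) >= threshold
    sens = float(pred[labels == 1].mean())
    spec = float((~pred[labels == 0]).mean())
    return sens, spec


def optimal_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximising sensitivity + specificity (Youden's J).

    Candidates are the smallest score (classify everything presence) and the
    midpoints of consecutive sorted unique scores; ties resolve to the
    smallest maximising threshold. Degenerate all-equal scores return that
    value with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("threshold requires both classes present")
    u = np.unique(scores)
    if len(u) == 1:
        warnings.warn("all scores identical; threshold is degenerate")
        return float(u[0])
    candidates = np.concatenate([[u[0]], (u[:-1] + u[1:]) / 2.0])
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        sens, spec = sens_spec(scores, labels, t)
        j = sens + spec
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


@dataclass
class MemberRecord:
    learner_id: str
    repetition: int
    auc: float
    included: bool


@dataclass
class EnsembleModel:
    members: list[MemberRecord]
    suitability: np.ndarray          # cell-wise median over included members
    threshold: float
    auc: float                       # AUC of the median ensemble on pooled points
    sensitivity: float
    specificity: float
    binary_map: BinaryRangeMap
    layer_names: list[str] = field(default_factory=list)

    @property
    def n_included(self) -> int:
        return sum(m.included for m in self.members)


def _stratified_split(labels: np.ndarray, train_frac: float, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for cls in (0, 1):
        idx = np.nonzero(labels == cls)[0]
        idx = rng.permutation(idx)
        n_train = max(1, min(len(idx) - 1, int(round(train_frac * len(idx)))))
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def run_ensemble(occ: OccurrenceSet, env: EnvStack, learners: list[str],
                 n_reps: int = 10, train_frac: float = 0.8, auc_min: float = 0.7,
                 seed: int = 0, background: OccurrenceSet | None = None,
                 layer_names: list[str] | None = None,
                 pa_ratio: int = 10) -> EnsembleModel:
    """Fit the repeated-split multi-learner ensemble and binarize it.

    occ must already be deduplicated. If no background set is supplied,
    pseudo-absences are drawn at pa_ratio x presences from a seed derived
    from ``seed``. Members with held-out AUC <= auc_min are excluded from the
    median; zero included members is an explicit failure listing member AUCs.
    """
    if not learners:
        raise ValueError("need at least one learner")
    layer_names = layer_names if layer_names is not None else env.layer_names
    ss = np.random.SeedSequence(seed)
    bg_seed, split_seed, learner_seed = (int(s.generate_state(1)[0]) % (2 ** 31)
                                         for s in ss.spawn(3))
    if background is None:
        background = generate_pseudoabsences(occ, env, ratio=pa_ratio, seed=bg_seed)

    pts = np.vstack([occ.points, background.points])
    labels = np.concatenate([np.ones(len(occ), dtype=int),
                             np.zeros(len(background), dtype=int)])
    X = env.values_at(pts[:, 0], pts[:, 1], layer_names)
    rows, cols, X_cells = env.valid_cell_features(layer_names)

    split_rng = np.random.default_rng(split_seed)
    members: list[MemberRecord] = []
    included_preds: list[np.ndarray] = []
    for rep in range(n_reps):
        tr, te = _stratified_split(labels, train_frac, split_rng)
        for li, lid in enumerate(learners):
            model = make_learner(lid, random_state=learner_seed + 1000 * rep + li)
            model.fit(X[tr], labels[tr])
            try:
                auc = evaluate_auc(model.predict_proba(X[te]), labels[te])
            except ValueError:
                auc = np.nan
            included = bool(np.isfinite(auc) and auc > auc_min)
            members.append(MemberRecord(lid, rep, float(auc), included))
            if included:
                included_preds.append(model.predict_proba(X_cells))

    if not included_preds:
        detail = ", ".join(f"{m.learner_id}/rep{m.repetition}: {m.auc:.3f}" for m in members)
        raise RuntimeError(f"no ensemble members passed AUC > {auc_min}; member AUCs: {detail}")

    median_cells = np.median(np.vstack(included_preds), axis=0)
    suit = np.full((env.geometry.n_rows, env.geometry.n_cols), np.nan)
    suit[rows, cols] = median_cells

    point_row, point_col = env.geometry.cell_of(pts[:, 0], pts[:, 1])
    point_scores = suit[point_row, point_col]
    threshold = optimal_threshold(point_scores, labels)
    ens_auc = evaluate_auc(point_scores, labels)
    sens, spec = sens_spec(point_scores, labels, threshold)

    presence = np.zeros_like(env.mask, dtype=bool)
    presence[env.mask] = suit[env.mask] >= threshold
    bmap = BinaryRangeMap(geometry=env.geometry, presence=presence,
                          mask=env.mask.copy(), threshold=threshold)
    return EnsembleModel(members=members, suitability=suit, threshold=threshold,
                         auc=ens_auc, sensitivity=sens, specificity=spec,
                         binary_map=bmap, layer_names=list(layer_names))
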