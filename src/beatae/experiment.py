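"""Evaluation protocol: splits, balancing, cross-validation, threshold
selection, classification metrics, and the end-to-end pipeline.

The protocol mirrors how beat-by-beat AFib detectors are evaluated:
signal portions (or patients) are split 80/20 into train and test, the
majority class is undersampled to the minority count in training only,
features are standardized with training statistics, model instances are
selected by 10-fold cross-validation (lowest validation loss), the
operating threshold is the Youden-optimal point of the validation ROC,
and the untouched, unbalanced test set yields the reported confusion
counts, accuracy, precision, recall, F1 and AUC.

The LCSD statistic is validated separately: a Mann-Whitney U test
between the NSR and AFib per-beat values, and a logistic-regression
baseline using LCSD as the sole feature.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import nnet, synthetic
from .features import Standardizer, attach_lcsd
from .nnet import TrainConfig, TrainResult
from .preprocess import preprocess_record
from .records import AFIB, NSR, BeatMatrix

__all__ = [
    "SplitPlan",
    "EvalReport",
    "MWUResult",
    "make_split",
    "balance_classes",
    "crossval_train",
    "select_threshold",
    "roc_points",
    "evaluate",
    "mannwhitney_u",
    "lcsd_baseline",
    "run_pipeline",
]

log = logging.getLogger(__name__)


# ------------------------------------------------------------------ splits

@dataclass(frozen=True)
class SplitPlan:
    """How to partition data into train and test.

    ``portion`` mode splits by signal portion (for synthetic and
    CinC-like data a portion is a record; for AFDB-like data a maximal
    same-label interval), stratified by class.  ``patient`` mode splits
    by patient id, so no patient contributes beats to both sides.
    """

    mode: str = "portion"
    train_fraction: float = 0.8
    seed: int = 0
    folds: int = 10

    def __post_init__(self):
        if self.mode not in ("portion", "patient"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train fraction must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")


def _portion_ids(matrix: BeatMatrix) -> np.ndarray:
    """Per-beat portion key: record id + rhythm label (a synthetic or
    CinC record is one portion; an AFDB record contributes one portion
    per rhythm label run, which its label encodes here)."""
    return np.array(
        [f"{r}|{l}" for r, l in zip(matrix.record_ids, matrix.labels)], dtype=object
    )


def make_split(matrix: BeatMatrix, plan: SplitPlan) -> tuple[np.ndarray, np.ndarray]:
    """Return (train_idx, test_idx) row indices under the plan.

    Portion mode samples portions stratified by their label; patient
    mode samples patient ids (>= 2 patients required).  The achieved
    train fraction is within one unit of the target at the unit level.
    """
    rng = np.random.default_rng(plan.seed)
    if plan.mode == "patient":
        patients = np.unique(matrix.patient_ids)
        if patients.size < 2:
            raise ValueError("patient mode needs at least 2 patients")
        order = rng.permutation(patients)
        n_train = int(round(plan.train_fraction * patients.size))
        n_train = min(max(n_train, 1), patients.size - 1)
        train_units = set(order[:n_train])
        mask = np.array([p in train_units for p in matrix.patient_ids])
    else:
        units = _portion_ids(matrix)
        uniq = np.unique(units)
        unit_label = {u: u.rsplit("|", 1)[1] for u in uniq}
        train_units = set()
        for lab in sorted(set(unit_label.values())):
            members = np.array([u for u in uniq if unit_label[u] == lab])
            order = rng.permutation(members)
            n_train = int(round(plan.train_fraction * members.size))
            n_train = min(max(n_train, 1), max(members.size - 1, 1))
            train_units.update(order[:n_train])
        mask = np.array([u in train_units for u in units])
    return np.flatnonzero(mask), np.flatnonzero(~mask)


def balance_classes(labels: np.ndarray, seed: int = 0) -> np.ndarray:
    """Undersample the majority class: returns sorted row indices with
    equal class counts, the minority class untouched."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("both classes must be present to balance")
    rng = np.random.default_rng(seed)
    counts = {c: np.flatnonzero(labels == c) for c in classes}
    n_min = min(idx.size for idx in counts.values())
    keep = []
    for c in sorted(counts):
        idx = counts[c]
        if idx.size > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


# --------------------------------------------------------- cross-validation

def crossval_train(
    spec: nnet.NetworkSpec,
    data: tuple,
    folds: int = 10,
    config: TrainConfig = TrainConfig(),
) -> dict:
    """Train one network per fold and keep the lowest-validation-loss run.

    ``data`` is ``(x, labels, aux)`` with labels/aux possibly None.  The
    fold partition is a seeded permutation split into ``folds`` parts;
    fold k serves as the validation set of run k (both for early
    stopping and for instance selection).  Returns a dict with the
    selected network, its TrainResult, the fold assignment, and the
    selected run's validation probabilities/labels (when the spec has a
    classifier head) for threshold selection.
    """
    x, y, aux = data
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[0]
    if n < folds:
        raise ValueError(f"{n} samples cannot fill {folds} folds")
    rng = np.random.default_rng(config.seed)
    assignment = np.repeat(np.arange(folds), np.diff(np.linspace(0, n, folds + 1).astype(int)))
    assignment = assignment[rng.permutation(n)]

    best = None
    all_results = []
    for k in range(folds):
        val_mask = assignment == k
        tr = (
            x[~val_mask],
            None if y is None else np.asarray(y)[~val_mask],
            None if aux is None else np.atleast_2d(np.asarray(aux))[~val_mask],
        )
        va = (
            x[val_mask],
            None if y is None else np.asarray(y)[val_mask],
            None if aux is None else np.atleast_2d(np.asarray(aux))[val_mask],
        )
        fold_seed = int((config.seed * 1009 + k) % (2**31))
        net = nnet.build_network(spec, seed=fold_seed)
        result = nnet.train(
            net, tr, va,
            TrainConfig(
                batch_size=config.batch_size,
                learning_rate=config.learning_rate,
                max_epochs=config.max_epochs,
                patience=config.patience,
                seed=fold_seed,
            ),
        )
        all_results.append(result)
        if best is None or result.best_val_loss < best["result"].best_val_loss:
            entry = {"network": net, "result": result, "fold": k}
            if spec.head:
                entry["val_probs"] = net.predict_proba(va[0], va[2])
                entry["val_labels"] = va[1]
            best = entry
    best["assignment"] = assignment
    best["fold_val_losses"] = [r.best_val_loss for r in all_results]
    return best


# ------------------------------------------------------------------ metrics

@dataclass
class EvalReport:
    """Confusion counts and the metrics derived from them, plus the ROC."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    roc: np.ndarray          # (k, 2) array of (fpr, tpr)
    threshold: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "auc": self.auc,
            "threshold": self.threshold, "degenerate": self.degenerate,
            "roc": np.asarray(self.roc).tolist(),
        }

    def to_json(self, path=None) -> str:
        blob = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(blob)
        return blob


def roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Full ROC as (fpr, tpr) points, one per distinct score plus the
    (0,0) and (1,1) anchors; equal scores are grouped so the trapezoidal
    area equals pairwise concordance with ties counted half."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    order = np.argsort(-scores, kind="stable")
    s, yy = scores[order], y[order]
    n_pos = int(yy.sum())
    n_neg = yy.size - n_pos
    tps, fps = [0], [0]
    i = 0
    while i < yy.size:
        j = i
        while j < yy.size and s[j] == s[i]:
            j += 1
        tps.append(tps[-1] + int(yy[i:j].sum()))
        fps.append(fps[-1] + (j - i) - int(yy[i:j].sum()))
        i = j
    tpr = np.array(tps) / max(n_pos, 1)
    fpr = np.array(fps) / max(n_neg, 1)
    return np.column_stack([fpr, tpr])


def auc_trapezoid(roc: np.ndarray) -> float:
    roc = np.asarray(roc, dtype=float)
    return float(np.trapezoid(roc[:, 1], roc[:, 0]))


def select_threshold(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1
    over the validation ROC; ties broken toward 0.5.

    Candidate thresholds are midpoints between consecutive distinct
    scores (plus one below the minimum and one above the maximum), so a
    perfectly separated score set yields a threshold inside the gap.
    Degenerate single-class labels give 0.5 with a warning.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        log.warning("select_threshold: single-class labels; returning 0.5")
        return 0.5
    distinct = np.unique(p)
    candidates = [(distinct[i] + distinct[i + 1]) / 2 for i in range(distinct.size - 1)]
    candidates = [max(distinct[0] / 2, 0.0)] + candidates + [
        min((distinct[-1] + 1.0) / 2, 1.0)
    ]
    n_pos = int((y == 1).sum())
    n_neg = y.size - n_pos
    best_t, best_j = 0.5, -np.inf
    for t in candidates:
        pred = p >= t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        j = tp / n_pos + (n_neg - fp) / n_neg - 1.0
        if j > best_j + 1e-15 or (
            abs(j - best_j) <= 1e-15 and abs(t - 0.5) < abs(best_t - 0.5)
        ):
            best_j, best_t = j, t
    if best_j <= 1e-9:
        log.warning("select_threshold: no threshold separates the classes (J ~ 0)")
    return float(min(max(best_t, 1e-9), 1 - 1e-9))


def evaluate(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float
) -> EvalReport:
    """Confusion counts at the threshold plus threshold-free ROC/AUC.

    AFib is the positive class (label 1).  Metrics whose denominator is
    zero are reported as 0 with the ``degenerate`` flag set.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.size != y.size:
        raise ValueError("probabilities and labels must have equal length")
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    n = y.size
    degenerate = False

    def _ratio(num, den):
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    accuracy = _ratio(tp + tn, n)
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    f1 = _ratio(2 * precision * recall, precision + recall) if (precision + recall) else 0.0
    if precision + recall == 0:
        degenerate = True
    roc = roc_points(p, y)
    return EvalReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        auc=auc_trapezoid(roc), roc=roc, threshold=float(threshold),
        degenerate=degenerate,
    )


# ----------------------------------------------------------- Mann-Whitney

@dataclass(frozen=True)
class MWUResult:
    """Mann-Whitney U with tie-corrected normal approximation.

    Convention: ``u`` counts pairs (a, b) with a > b plus half-ties
    (i.e., U of the first group); U = 0 means every value in A is below
    every value in B.
    """

    u: float
    z: float
    p: float
    n1: int
    n2: int


def mannwhitney_u(a: np.ndarray, b: np.ndarray) -> MWUResult:
    """Rank-based U with midrank ties, tie-corrected sigma, continuity
    correction, and a two-sided normal-approximation p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    both = np.concatenate([a, b])
    ranks = stats.rankdata(both)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(both, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return MWUResult(u=float(u), z=0.0, p=1.0, n1=n1, n2=n2)
    # continuity correction toward the mean
    numerator = u - mu
    cc = 0.5 * np.sign(numerator)
    z = (numerator - cc) / np.sqrt(sigma2)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return MWUResult(u=float(u), z=float(z), p=p, n1=n1, n2=n2)


# ------------------------------------------------------------- LCSD baseline

def lcsd_baseline(
    train_matrix: BeatMatrix,
    test_matrix: BeatMatrix,
    config: TrainConfig = TrainConfig(),
) -> EvalReport:
    """Logistic regression on the LCSD value alone (a zero-hidden-layer
    network), trained with an internal 80/20 validation carve-out for
    early stopping and threshold selection, evaluated on the test set."""
    for m in (train_matrix, test_matrix):
        if m.lcsd is None:
            raise ValueError("LCSD column missing; run attach_lcsd first")
    x_tr = train_matrix.lcsd[:, None]
    y_tr = (train_matrix.labels == AFIB).astype(float)
    if np.ptp(x_tr) == 0:
        log.warning("lcsd_baseline: constant LCSD; classifier is degenerate")
    scaler = Standardizer().fit(x_tr)
    x_tr = scaler.transform(x_tr)
    x_te = scaler.transform(test_matrix.lcsd[:, None])
    y_te = (test_matrix.labels == AFIB).astype(float)

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(x_tr.shape[0])
    n_val = max(1, int(round(0.2 * order.size)))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    net = nnet.build_network(nnet.logistic_spec(1), seed=config.seed)
    nnet.train(
        net,
        (x_tr[tr_idx], y_tr[tr_idx], None),
        (x_tr[val_idx], y_tr[val_idx], None),
        config,
    )
    threshold = select_threshold(net.predict_proba(x_tr[val_idx]), y_tr[val_idx])
    return evaluate(net.predict_proba(x_te), y_te, threshold)


# ------------------------------------------------------------- the pipeline

DEFAULT_CONFIG = {
    "data": {
        "source": "synthetic",
        "n_records_per_class": 10,
        "duration": 30.0,
        "fs": 250.0,
        "patients": None,
        "patient_variation": False,
        "seed": 0,
    },
    "preprocess": {"dmean_threshold": 0.2},
    "model": {"family": "supae", "use_lcsd": True, "l1_code": 1e-4,
              "compression": 0.75, "head": [3, 1]},
    "split": {"mode": "portion", "train_fraction": 0.8, "folds": 10, "seed": 0},
    "train": {"batch_size": 32, "learning_rate": 1e-4, "max_epochs": 2000,
              "patience": 50, "seed": 0},
}


def _resolve_config(config: dict) -> dict:
    resolved = copy.deepcopy(DEFAULT_CONFIG)
    for section, values in (config or {}).items():
        if section not in resolved:
            raise KeyError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise TypeError(f"config section {section!r} must be a mapping")
        for key, val in values.items():
            if key not in resolved[section]:
                raise KeyError(f"unknown config key {section}.{key}")
            resolved[section][key] = val
    return resolved


def build_beat_matrix(config: dict) -> tuple[BeatMatrix, dict]:
    """Generate (or load) records, run preprocessing, attach LCSD.

    Returns the pooled beat matrix and the per-recording R-time series.
    Beats with undefined LCSD (recording endpoints) are always dropped
    so every model family and feature set sees the same beat population.
    """
    data = config["data"]
    if data["source"] != "synthetic":
        raise ValueError(
            "run_pipeline builds synthetic data; ingest real records with "
            "beatae.ingest and assemble a BeatMatrix explicitly"
        )
    records = synthetic.generate_dataset(
        n_records_per_class=data["n_records_per_class"],
        duration=data["duration"],
        fs=data["fs"],
        patients=data["patients"],
        patient_variation=(
            synthetic.PatientVariation() if data["patient_variation"] else None
        ),
        seed=data["seed"],
    )
    matrices, series = [], {}
    for rec in records:
        matrix, rpeaks = preprocess_record(
            rec, dmean_threshold=config["preprocess"]["dmean_threshold"]
        )
        if len(matrix) == 0:
            continue
        series[rec.record_id] = rpeaks / rec.fs
        matrices.append(matrix)
    pooled = BeatMatrix.concatenate(matrices)
    pooled = attach_lcsd(pooled, series, drop_undefined=True)
    return pooled, series


def run_pipeline(config: dict | None = None) -> dict:
    """Execute the full protocol and return a results bundle.

    The bundle holds the test-set :class:`EvalReport`, the selected
    training curves, LCSD validation results (Mann-Whitney U and the
    logistic baseline), and a manifest — the fully resolved config —
    from which ``run_pipeline(bundle["manifest"])`` re-executes
    bit-identically.
    """
    cfg = _resolve_config(config)
    matrix, _series = build_beat_matrix(cfg)

    plan = SplitPlan(
        mode=cfg["split"]["mode"],
        train_fraction=cfg["split"]["train_fraction"],
        folds=cfg["split"]["folds"],
        seed=cfg["split"]["seed"],
    )
    train_idx, test_idx = make_split(matrix, plan)
    train_m, test_m = matrix.take(train_idx), matrix.take(test_idx)

    bal_idx = balance_classes(train_m.labels, seed=cfg["split"]["seed"])
    train_m = train_m.take(bal_idx)

    # standardize waveform samples and the LCSD column jointly on training rows
    scaler = Standardizer().fit(
        np.column_stack([train_m.samples, train_m.lcsd])
    )
    def _standardized(m: BeatMatrix) -> tuple[np.ndarray, np.ndarray]:
        z = scaler.transform(np.column_stack([m.samples, m.lcsd]))
        return z[:, :-1], z[:, -1:]

    x_tr, lcsd_tr = _standardized(train_m)
    x_te, lcsd_te = _standardized(test_m)
    y_tr = (train_m.labels == AFIB).astype(float)
    y_te = (test_m.labels == AFIB).astype(float)

    model_cfg = cfg["model"]
    use_lcsd = bool(model_cfg["use_lcsd"])
    tconf = TrainConfig(
        batch_size=cfg["train"]["batch_size"],
        learning_rate=cfg["train"]["learning_rate"],
        max_epochs=cfg["train"]["max_epochs"],
        patience=cfg["train"]["patience"],
        seed=cfg["train"]["seed"],
    )
    width = x_tr.shape[1]
    folds = cfg["split"]["folds"]
    results: dict = {}

    if model_cfg["family"] == "supae":
        spec = nnet.supae_spec(
            width,
            compression=model_cfg["compression"],
            l1_code=model_cfg["l1_code"],
            aux_dim=1 if use_lcsd else 0,
            head=tuple(model_cfg["head"]),
        )
        best = crossval_train(
            spec, (x_tr, y_tr, lcsd_tr if use_lcsd else None), folds, tconf
        )
        network = best["network"]
        threshold = select_threshold(best["val_probs"], best["val_labels"])
        probs_te = network.predict_proba(x_te, lcsd_te if use_lcsd else None)
        results["train_results"] = {"supae": best["result"]}
    elif model_cfg["family"] == "ae":
        # stage 1: sparse AE on the waveforms alone
        ae = crossval_train(
            nnet.sae_spec(width, compression=model_cfg["compression"],
                          l1_code=model_cfg["l1_code"]),
            (x_tr, None, None), folds, tconf,
        )
        codes_tr = ae["network"].encode(x_tr)
        codes_te = ae["network"].encode(x_te)
        feats_tr = np.column_stack([codes_tr, lcsd_tr]) if use_lcsd else codes_tr
        feats_te = np.column_stack([codes_te, lcsd_te]) if use_lcsd else codes_te
        # stage 2: MLP classifier on the encoded features
        mlp = crossval_train(
            nnet.mlp_spec(feats_tr.shape[1], head=tuple(model_cfg["head"])),
            (feats_tr, y_tr, None), folds, tconf,
        )
        network = mlp["network"]
        threshold = select_threshold(mlp["val_probs"], mlp["val_labels"])
        probs_te = network.predict_proba(feats_te)
        results["train_results"] = {"sae": ae["result"], "mlp": mlp["result"]}
    else:
        raise ValueError(f"unknown model family {model_cfg['family']!r}")

    report = evaluate(probs_te, y_te, threshold)

    # LCSD statistical validation on the pooled beats
    nsr_lcsd = matrix.lcsd[matrix.labels == NSR]
    afib_lcsd = matrix.lcsd[matrix.labels == AFIB]
    mwu = mannwhitney_u(nsr_lcsd, afib_lcsd)

    results.update(
        report=report,
        mwu=mwu,
        threshold=threshold,
        n_train=len(train_m),
        n_test=len(test_m),
        test_patients=sorted(set(test_m.patient_ids)),
        test_units=sorted(set(_portion_ids(test_m))),
        manifest=cfg,
    )
    return results
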