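"""Sequence-computable intron features and the intron-class neural network.

Features per intron (all derivable from genome + annotation alone):
log10 intron length, intron GC fraction, relative position within the
transcript (ordinal / intron count), donor and acceptor splice-site
strengths as PWM log-odds (bits), and log10 length + GC of the flanking
(transcript-orientation upstream/downstream) exons. Splice-site PWMs
are estimated from the catalog's own annotated introns with pseudocount
1 against a uniform background.

The classifier distinguishing NCI / CIR / LIR introns is a feed-forward
network with three hidden layers (default 64/32/16, ReLU, softmax
output) trained on standardized features; evaluation is pairwise
one-vs-one AUROC / AUPRC plus permutation feature importance.

External feature tracks (conservation, structure, motif databases,
nucleosome positioning) are not computed here; ``train_classifier``
accepts any extra numeric columns supplied by the user.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .model import Genome, Interval, IntronInterval, Transcript, TranscriptCatalog

CLASS_LABELS = ("NCI", "CIR", "LIR")
PAIRS = (("NCI", "LIR"), ("NCI", "CIR"), ("LIR", "CIR"))

FEATURE_NAMES = [
    "intron_length_log10",
    "intron_gc",
    "relative_position",
    "donor_ss_score",
    "acceptor_ss_score",
    "upstream_exon_length_log10",
    "downstream_exon_length_log10",
    "upstream_exon_gc",
    "downstream_exon_gc",
]

# Window geometry around the splice sites, in transcript orientation:
# donor = 3 exonic + 6 intronic nt (…exon]GTxxxx), acceptor = 20 intronic
# + 3 exonic nt (xxxxAG[exon…).
DONOR_EXONIC, DONOR_INTRONIC = 3, 6
ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC = 20, 3

_BASES = "ACGT"


@dataclass
class SpliceSitePWM:
    """Position weight matrix scorer: log2 odds vs uniform background."""

    log_odds: np.ndarray  # (positions, 4)

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    def score(self, window: str) -> float:
        if len(window) != self.width:
            raise ValueError(f"window length {len(window)} != PWM width {self.width}")
        total = 0.0
        for i, base in enumerate(window):
            j = _BASES.find(base)
            if j >= 0:  # N scores 0 (background)
                total += self.log_odds[i, j]
        return float(total)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @classmethod
    def from_windows(cls, windows: list[str], pseudocount: float = 1.0) -> "SpliceSitePWM":
        if not windows:
            raise ValueError("no training windows for PWM")
        width = len(windows[0])
        counts = np.full((width, 4), pseudocount)
        for w in windows:
            if len(w) != width:
                raise ValueError("inconsistent window lengths")
            for i, base in enumerate(w):
                j = _BASES.find(base)
                if j >= 0:
                    counts[i, j] += 1
        freqs = counts / counts.sum(axis=1, keepdims=True)
        return cls(np.log2(freqs / 0.25))


def _donor_window(intron: Interval, strand: str, genome: Genome) -> str:
    if strand != "-":
        iv = Interval(intron.contig, intron.start - DONOR_EXONIC,
                      intron.start + DONOR_INTRONIC, "+")
        return genome.fetch(iv)
    iv = Interval(intron.contig, intron.end - DONOR_INTRONIC,
                  intron.end + DONOR_EXONIC, "-")
    return genome.fetch(iv)


def _acceptor_window(intron: Interval, strand: str, genome: Genome) -> str:
    if strand != "-":
        iv = Interval(intron.contig, intron.end - ACCEPTOR_INTRONIC,
                      intron.end + ACCEPTOR_EXONIC, "+")
        return genome.fetch(iv)
    iv = Interval(intron.contig, intron.start - ACCEPTOR_EXONIC,
                  intron.start + ACCEPTOR_INTRONIC, "-")
    return genome.fetch(iv)


def train_pwms(
    catalog: TranscriptCatalog, genome: Genome, pseudocount: float = 1.0
) -> tuple[SpliceSitePWM, SpliceSitePWM]:
    """Estimate donor and acceptor PWMs from all annotated introns."""
    donors, acceptors = [], []
    for t in catalog:
        for intron in t.introns():
            try:
                donors.append(_donor_window(intron.interval, t.strand, genome))
                acceptors.append(_acceptor_window(intron.interval, t.strand, genome))
            except (ValueError, IndexError):
                continue  # window off contig edge
    return SpliceSitePWM.from_windows(donors, pseudocount), SpliceSitePWM.from_windows(
        acceptors, pseudocount
    )


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def _flanking_exons(transcript: Transcript, intron: Interval) -> tuple[Interval, Interval]:
    """(upstream, downstream) exons in transcript orientation."""
    left = right = None
    for exon in transcript.exons:
        if exon.end == intron.start:
            left = exon
        if exon.start == intron.end:
            right = exon
    if left is None or right is None:
        raise ValueError(
            f"intron [{intron.start},{intron.end}) does not sit between exons "
            f"of {transcript.transcript_id}"
        )
    return (left, right) if transcript.strand != "-" else (right, left)


def extract_features(
    intron: IntronInterval,
    catalog: TranscriptCatalog,
    genome: Genome,
    pwms: tuple[SpliceSitePWM, SpliceSitePWM],
) -> dict[str, float]:
    t = catalog.get(intron.transcript_id)
    n_introns = len(t.introns())
    iv = intron.interval
    up, down = _flanking_exons(t, iv)
    donor_pwm, acceptor_pwm = pwms
    plus = Interval(iv.contig, iv.start, iv.end, "+")
    return {
        "intron_length_log10": float(np.log10(len(iv))),
        "intron_gc": gc_fraction(genome.fetch(plus)),
        "relative_position": intron.ordinal / n_introns,
        "donor_ss_score": donor_pwm.score(_donor_window(iv, t.strand, genome)),
        "acceptor_ss_score": acceptor_pwm.score(_acceptor_window(iv, t.strand, genome)),
        "upstream_exon_length_log10": float(np.log10(len(up))),
        "downstream_exon_length_log10": float(np.log10(len(down))),
        "upstream_exon_gc": gc_fraction(genome.fetch(Interval(up.contig, up.start, up.end, "+"))),
        "downstream_exon_gc": gc_fraction(genome.fetch(Interval(down.contig, down.start, down.end, "+"))),
    }


def feature_table(
    introns: list[IntronInterval],
    catalog: TranscriptCatalog,
    genome: Genome,
    pwms: tuple[SpliceSitePWM, SpliceSitePWM] | None = None,
) -> pd.DataFrame:
    if pwms is None:
        pwms = train_pwms(catalog, genome)
    rows = []
    for intron in introns:
        row = {"intron_id": intron.name}
        row.update(extract_features(intron, catalog, genome, pwms))
        rows.append(row)
    return pd.DataFrame(rows).set_index("intron_id")


@dataclass
class ClassifierModel:
    scaler: StandardScaler
    network: MLPClassifier
    feature_names: list[str]
    seed: int
    version: str = "1"

    def predict_proba(self, X: pd.DataFrame) -> pd.DataFrame:
        Z = self.scaler.transform(X[self.feature_names].values)
        proba = self.network.predict_proba(Z)
        return pd.DataFrame(proba, index=X.index, columns=self.network.classes_)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        proba = self.predict_proba(X)
        return proba.idxmax(axis=1)

    def save(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "seed": self.seed,
            "feature_names": self.feature_names,
            "classes": list(self.network.classes_),
            "scaler_mean": self.scaler.mean_.tolist(),
            "scaler_scale": self.scaler.scale_.tolist(),
            "coefs": [w.tolist() for w in self.network.coefs_],
            "intercepts": [b.tolist() for b in self.network.intercepts_],
            "hidden_layer_sizes": list(self.network.hidden_layer_sizes),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        with open(path) as fh:
            payload = json.load(fh)
        scaler = StandardScaler()
        scaler.mean_ = np.array(payload["scaler_mean"])
        scaler.scale_ = np.array(payload["scaler_scale"])
        scaler.var_ = scaler.scale_**2
        scaler.n_features_in_ = scaler.mean_.size
        net = MLPClassifier(hidden_layer_sizes=tuple(payload["hidden_layer_sizes"]))
        net.coefs_ = [np.array(w) for w in payload["coefs"]]
        net.intercepts_ = [np.array(b) for b in payload["intercepts"]]
        net.classes_ = np.array(payload["classes"])
        net.n_layers_ = len(net.coefs_) + 1
        net.n_outputs_ = len(net.classes_)
        net.out_activation_ = "softmax" if net.n_outputs_ > 2 else "logistic"
        net._label_binarizer = None
        model = cls(scaler, net, payload["feature_names"], payload["seed"],
                    payload["version"])
        return model


@dataclass
class SplitData:
    train: pd.DataFrame
    val: pd.DataFrame
    test: pd.DataFrame


def stratified_split(
    dataset: pd.DataFrame,
    seed: int,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    label_col: str = "label",
) -> SplitData:
    f_train, f_val, f_test = fractions
    rest, test = train_test_split(
        dataset, test_size=f_test, random_state=seed, stratify=dataset[label_col]
    )
    val_frac = f_val / (f_train + f_val)
    train, val = train_test_split(
        rest, test_size=val_frac, random_state=seed + 1, stratify=rest[label_col]
    )
    return SplitData(train, val, test)


def _balance_by_oversampling(
    X: np.ndarray, y: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic inverse-frequency oversampling to class balance.

    Equivalent in expectation to inverse-frequency loss weighting, which
    the underlying network cannot take directly.
    """
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    idx_all = []
    for cls, cnt in zip(classes, counts):
        idx = np.flatnonzero(y == cls)
        reps = target // cnt
        extra = target - reps * cnt
        chosen = np.concatenate([np.tile(idx, reps),
                                 rng.choice(idx, extra, replace=False)])
        idx_all.append(chosen)
    order = np.concatenate(idx_all)
    order = order[rng.permutation(order.size)]
    return X[order], y[order]


def train_classifier(
    dataset: pd.DataFrame,
    seed: int = 0,
    hidden_layer_sizes: tuple[int, ...] = (64, 32, 16),
    max_iter: int = 400,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    label_col: str = "label",
) -> tuple[ClassifierModel, SplitData]:
    """Train the three-hidden-layer network on a labeled feature table.

    Standardization parameters come from the training split only; class
    imbalance is handled by oversampling the training split to balance.
    Returns the model and the stratified train/val/test split.
    """
    labels = dataset[label_col]
    if labels.nunique() < 2:
        raise ValueError("need at least 2 classes to train")
    feature_names = [c for c in dataset.columns if c != label_col]
    split = stratified_split(dataset, seed, fractions, label_col)
    scaler = StandardScaler().fit(split.train[feature_names].values)
    Xtr = scaler.transform(split.train[feature_names].values)
    ytr = split.train[label_col].values
    Xtr, ytr = _balance_by_oversampling(Xtr, ytr, seed)
    net = MLPClassifier(
        hidden_layer_sizes=hidden_layer_sizes,
        activation="relu",
        solver="adam",
        max_iter=max_iter,
        random_state=seed,
        early_stopping=False,
    )
    net.fit(Xtr, ytr)
    return ClassifierModel(scaler, net, feature_names, seed), split


@dataclass
class PairMetrics:
    auroc: float | None
    auprc: float | None
    positive: str


@dataclass
class EvalReport:
    pairwise: dict[tuple[str, str], PairMetrics]
    importance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_json(self) -> str:
        payload = {
            "pairwise": {
                f"{a}_vs_{b}": {
                    "auroc": m.auroc, "auprc": m.auprc, "positive": m.positive
                }
                for (a, b), m in self.pairwise.items()
            },
            "importance": self.importance.round(6).to_dict(orient="index"),
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def _pair_auroc(
    model: ClassifierModel, test: pd.DataFrame, pair: tuple[str, str],
    label_col: str = "label",
) -> tuple[float | None, float | None]:
    a, b = pair
    sub = test[test[label_col].isin(pair)]
    if (sub[label_col] == a).sum() < 2 or (sub[label_col] == b).sum() < 2:
        return None, None
    proba = model.predict_proba(sub)
    y = (sub[label_col] == b).astype(int).values
    scores = proba[b].values
    return (
        float(roc_auc_score(y, scores)),
        float(average_precision_score(y, scores)),
    )


def evaluate(
    model: ClassifierModel,
    test: pd.DataFrame,
    pairs: tuple = PAIRS,
    n_permutations: int = 20,
    seed: int = 0,
    label_col: str = "label",
) -> EvalReport:
    """Pairwise one-vs-one AUROC/AUPRC plus permutation feature importance.

    For each feature, importance per pair is the mean AUROC drop over
    ``n_permutations`` shuffles of that feature column in the test set;
    the association sign comes from the point-biserial correlation of
    the feature with the (second-named = positive) class indicator.
    """
    present_pairs = [p for p in pairs if set(p) <= set(test[label_col].unique())]
    pairwise = {}
    for pair in pairs:
        if pair not in present_pairs:
            pairwise[pair] = PairMetrics(None, None, pair[1])
            continue
        auroc, auprc = _pair_auroc(model, test, pair, label_col)
        pairwise[pair] = PairMetrics(auroc, auprc, pair[1])

    if n_permutations < 1:
        return EvalReport(pairwise, pd.DataFrame())
    rng = np.random.default_rng(seed)
    rows = {}
    for feat in model.feature_names:
        row = {}
        for pair in present_pairs:
            base = pairwise[pair].auroc
            if base is None:
                continue
            drops = []
            for _ in range(n_permutations):
                shuffled = test.copy()
                shuffled[feat] = rng.permutation(shuffled[feat].values)
                perm_auroc, _ = _pair_auroc(model, shuffled, pair, label_col)
                drops.append(base - (perm_auroc if perm_auroc is not None else 0.5))
            sub = test[test[label_col].isin(pair)]
            y = (sub[label_col] == pair[1]).astype(int).values
            x = sub[feat].values
            sign = 0.0
            if y.min() != y.max() and np.std(x) > 0:
                sign = float(np.sign(stats.pointbiserialr(y, x).correlation))
            key = f"{pair[0]}_vs_{pair[1]}"
            row[f"importance_{key}"] = float(np.mean(drops))
            row[f"sign_{key}"] = sign
        rows[feat] = row
    return EvalReport(pairwise, pd.DataFrame.from_dict(rows, orient="index"))


def write_report(report: EvalReport, tsv_path: str | Path, json_path: str | Path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("pair\tpositive\tauroc\tauprc\n")
        for (a, b), m in report.pairwise.items():
            auroc = f"{m.auroc:.4f}" if m.auroc is not None else "NA"
            auprc = f"{m.auprc:.4f}" if m.auprc is not None else "NA"
            fh.write(f"{a}_vs_{b}\t{m.positive}\t{auroc}\t{auprc}\n")
    with open(json_path, "w") as fh:
        fh.write(report.to_json())
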