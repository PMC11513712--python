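"""RNAi resistance-index signatures and mechanism-of-action classification.

A drug's signature is the vector of resistance indices (RI) of eight
shRNA-bearing GFP+ populations competing against untransduced cells under
near-lethal drug exposure.  With ``G_t``/``G_c`` the GFP+ fractions in the
treated and control arms,

    RI = (G_t - G_t G_c) / (G_c - G_t G_c) = [G_t/(1-G_t)] / [G_c/(1-G_c)]

i.e. the odds ratio of carrying the hairpin after treatment; RI > 1 means
the knockdown protects, RI < 1 sensitizes.  Query signatures are classified
against a labeled reference set by Euclidean k-nearest neighbors; confidence
is a linkage ratio (LR) comparing the query's distance to the called class
against that class's internal spread, with a label-permutation p-value.
LR <= 1 with p < 0.05 is a confident call, anything else a "new class".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateMeasurementError,
    InvalidInputError,
    RosterError,
)

#: Fixed hairpin roster defining the signature coordinate order.  Only the
#: second entry (shCHK2) is fixed by convention; the roster is configurable.
DEFAULT_ROSTER = (
    "shp53",
    "shCHK2",
    "shCHK1",
    "shATR",
    "shATX",
    "shDNAPK",
    "shBOK",
    "shBIM",
)

NEW_CLASS = "NEW_CLASS"


@dataclass
class CompetitionMeasurement:
    hairpin: str
    gfp_treated: float
    gfp_control: float
    drug: str = ""
    dose_tag: str = "LD80-90"


def resistance_index(measurement: CompetitionMeasurement | None = None,
                     gfp_treated: float | None = None,
                     gfp_control: float | None = None) -> float:
    """RI from GFP+ fractions, computed in the stable odds-ratio form."""
    if measurement is not None:
        gfp_treated = measurement.gfp_treated
        gfp_control = measurement.gfp_control
    gt = float(gfp_treated)
    gc = float(gfp_control)
    if not (0.0 <= gt <= 1.0 and 0.0 <= gc <= 1.0):
        raise InvalidInputError("GFP values must be fractions in [0, 1]")
    if gt == 1.0 or gc in (0.0, 1.0):
        raise DegenerateMeasurementError(
            f"RI undefined for gfp_treated={gt}, gfp_control={gc}"
        )
    return (gt * (1.0 - gc)) / (gc * (1.0 - gt))


@dataclass
class Signature:
    """8-hairpin RI vector in fixed roster order."""

    drug: str
    ri: np.ndarray
    roster: tuple = DEFAULT_ROSTER

    def __post_init__(self):
        self.ri = np.asarray(self.ri, dtype=float)
        if self.ri.shape != (len(self.roster),):
            raise RosterError(
                f"signature for {self.drug!r} has {self.ri.size} entries, "
                f"roster needs {len(self.roster)}"
            )
        if not np.all(np.isfinite(self.ri)):
            raise InvalidInputError(f"non-finite RI in signature for {self.drug!r}")


def build_signature(
    measurements, drug: str = "", roster: tuple = DEFAULT_ROSTER
) -> Signature:
    """Assemble a signature from competition measurements.

    ``measurements`` is an iterable of ``CompetitionMeasurement`` or a
    DataFrame with columns hairpin/gfp_treated/gfp_control (optionally
    pre-computed ``ri``).  Replicates per hairpin are averaged; every roster
    hairpin must be present and no hairpin may fall outside the roster.
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements.copy()
        if "ri" not in df.columns:
            df["ri"] = [
                resistance_index(gfp_treated=t, gfp_control=c)
                for t, c in zip(df["gfp_treated"], df["gfp_control"])
            ]
    else:
        rows = [
            {"hairpin": m.hairpin, "ri": resistance_index(m)} for m in measurements
        ]
        df = pd.DataFrame(rows)
    unknown = set(df["hairpin"]) - set(roster)
    if unknown:
        raise RosterError(f"hairpins not in roster: {sorted(unknown)}")
    means = df.groupby("hairpin")["ri"].mean()
    missing = [h for h in roster if h not in means.index]
    if missing:
        raise RosterError(f"missing roster hairpins: {missing}")
    return Signature(drug=drug, ri=means.reindex(list(roster)).to_numpy(), roster=roster)


@dataclass
class ReferenceSet:
    """Labeled reference signatures; >= 2 classes, >= 2 members per class."""

    signatures: list[Signature]
    labels: list[str]

    def __post_init__(self):
        if len(self.signatures) != len(self.labels):
            raise InvalidInputError("signatures and labels lengths differ")
        rosters = {s.roster for s in self.signatures}
        if len(rosters) > 1:
            raise RosterError("reference signatures use different hairpin rosters")
        counts = pd.Series(self.labels).value_counts()
        if len(counts) < 2:
            raise InvalidInputError("reference set needs >= 2 classes")
        if counts.min() < 2:
            raise InvalidInputError("every reference class needs >= 2 members")

    @property
    def matrix(self) -> np.ndarray:
        return np.vstack([s.ri for s in self.signatures])

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def smallest_class_size(self) -> int:
        return int(pd.Series(self.labels).value_counts().min())


@dataclass
class ClassificationResult:
    predicted_class: str
    candidate_class: str
    lr: float
    p: float
    k_used: int

    def summary(self) -> str:
        verdict = (
            f"classified as {self.predicted_class!r}"
            if self.predicted_class != NEW_CLASS
            else f"NEW CLASS (nearest category {self.candidate_class!r})"
        )
        return (
            "Signature classification\n========================\n"
            f"{verdict}\nlinkage ratio  {self.lr:.4g}\np value        {self.p:.4g}\n"
            f"k              {self.k_used}"
        )


def _query_numerator(query_dist: np.ndarray, members: np.ndarray, k: int) -> float:
    kq = min(k, len(members))
    return float(np.sort(query_dist[members])[:kq].mean())


def _within_denominator(ref_dist: np.ndarray, members: np.ndarray, k: int) -> float:
    within = []
    for m in members:
        others = members[members != m]
        km = min(k, len(others))
        within.append(float(np.sort(ref_dist[m, others])[:km].mean()))
    return float(np.mean(within))


def _vote(query_dist: np.ndarray, labels: np.ndarray, k: int) -> str:
    order = np.argsort(query_dist, kind="stable")[:k]
    top_labels = labels[order]
    counts = pd.Series(top_labels).value_counts()
    best = counts.max()
    tied = sorted(counts.index[counts == best])
    if len(tied) > 1:
        means = {c: float(query_dist[order[top_labels == c]].mean()) for c in tied}
        low = min(means.values())
        tied = sorted(c for c in tied if means[c] == low)
    return tied[0]


def _classify_distances(
    query_dist: np.ndarray, ref_dist: np.ndarray, labels: np.ndarray, k: int
) -> tuple[str, float, float, float]:
    predicted = _vote(query_dist, labels, k)
    members = np.nonzero(labels == predicted)[0]
    num = _query_numerator(query_dist, members, k)
    den = _within_denominator(ref_dist, members, k)
    if den == 0:
        # identical reference members: any nonzero query distance is "far"
        lr = 0.0 if num == 0 else np.inf
    else:
        lr = num / den
    return predicted, lr, num, den


def _distances(query: Signature, ref: ReferenceSet) -> tuple[np.ndarray, np.ndarray]:
    if query.roster != ref.signatures[0].roster:
        raise RosterError("query and reference hairpin rosters differ")
    mat = ref.matrix
    dq = np.linalg.norm(mat - query.ri, axis=1)
    diff = mat[:, None, :] - mat[None, :, :]
    dref = np.linalg.norm(diff, axis=2)
    return dq, dref


def knn_classify(query: Signature, ref: ReferenceSet, k: int = 3) -> tuple[str, float]:
    """Majority-vote Euclidean KNN plus the linkage ratio of the called class.

    The LR is the mean distance from the query to its k nearest members of
    the predicted class, divided by the class's mean leave-one-out k-nearest
    within-class distance; LR <= 1 means the query sits inside the class's
    own spread.
    """
    if k < 1 or k > ref.smallest_class_size():
        raise InvalidInputError(
            f"k must be in [1, smallest class size = {ref.smallest_class_size()}]"
        )
    dq, dref = _distances(query, ref)
    labels = np.asarray(ref.labels)
    predicted, lr, _, _ = _classify_distances(dq, dref, labels, k)
    return predicted, lr


def permutation_pvalue(
    query: Signature,
    ref: ReferenceSet,
    k: int = 3,
    B: int = 999,
    seed: int = 0,
) -> float:
    """Label-permutation p-value for the observed classification.

    Class labels of the reference set are shuffled B times (class sizes
    preserved); each time the KNN vote is re-run and the query's k-nearest
    mean distance to the re-voted class recomputed.  The observed
    within-class spread serves as a fixed normalizer, so the test asks how
    often random labels place the query as close to a class as the true
    labels do: p = (1 + #{lr_perm <= lr_obs}) / (B + 1), with minimum
    attainable p of 1/(B+1).  Under label-free references the observed
    labeling is one more permutation, so p is uniform.
    """
    dq, dref = _distances(query, ref)
    labels = np.asarray(ref.labels)
    _, _, num_obs, _ = _classify_distances(dq, dref, labels, k)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(B):
        perm = labels[rng.permutation(len(labels))]
        cls_perm = _vote(dq, perm, k)
        num_perm = _query_numerator(dq, np.nonzero(perm == cls_perm)[0], k)
        if num_perm <= num_obs:
            hits += 1
    return (1.0 + hits) / (B + 1.0)


def is_confident(lr: float, p: float, lr_threshold: float = 1.0, p_threshold: float = 0.05) -> bool:
    """The published call rule: LR <= 1 and p < 0.05 (boundary LR = 1 passes)."""
    return lr <= lr_threshold and p < p_threshold


def classify_drug(
    query: Signature,
    ref: ReferenceSet,
    k: int = 3,
    B: int = 999,
    seed: int = 0,
    lr_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> ClassificationResult:
    """Full classification: KNN call, LR, permutation p, new-class rule."""
    candidate, lr = knn_classify(query, ref, k=k)
    p = permutation_pvalue(query, ref, k=k, B=B, seed=seed)
    predicted = candidate if is_confident(lr, p, lr_threshold, p_threshold) else NEW_CLASS
    return ClassificationResult(
        predicted_class=predicted, candidate_class=candidate, lr=float(lr), p=float(p), k_used=k
    )
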