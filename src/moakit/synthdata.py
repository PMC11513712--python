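"""Synthetic-data generators for every pipeline stage, with known ground truth.

Each generator is a pure function of its truth object and seed, so every
downstream stage can be tested against planted parameters without external
data:

* constant-ratio dose-response plates built on 4PL single-agent curves with
  a Loewe-additive, synergistic (potency-shift) or antagonistic combination
  surface;
* SYTOX-style live/dead time courses with exponential population growth and
  lag-exponential death;
* negative-binomial sgRNA count tables for a TKOv3-like library with planted
  essential and death-modifier genes;
* 8-hairpin resistance-index signatures around labeled class centroids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import InvalidInputError
from .flick import PopulationTimecourse
from .screen import NONTARGETING, GuideCountMatrix
from .signature import DEFAULT_ROSTER, ReferenceSet, Signature

# ---------------------------------------------------------------------------
# truth objects
# ---------------------------------------------------------------------------

INTERACTION_MODES = ("loewe_additive", "synergy", "antagonism")


@dataclass
class SynergyTruth:
    """Ground truth for a two-drug constant-ratio dose-response experiment."""

    ec50_a: float = 1.0
    ec50_b: float = 10.0
    hill_a: float = 1.0
    hill_b: float = 1.0
    interaction_mode: str = "loewe_additive"
    interaction_strength: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.ec50_a <= 0 or self.ec50_b <= 0:
            raise InvalidInputError("ec50 values must be positive")
        if self.hill_a <= 0 or self.hill_b <= 0:
            raise InvalidInputError("hill slopes must be positive")
        if self.interaction_mode not in INTERACTION_MODES:
            raise InvalidInputError(f"unknown interaction mode {self.interaction_mode!r}")
        if self.interaction_strength < 0 or self.noise_sd < 0:
            raise InvalidInputError("interaction_strength and noise_sd must be >= 0")

    @property
    def fraction_a(self) -> float:
        """Default design ratio: drug A's dose fraction at the EC50 ratio."""
        return self.ec50_a / (self.ec50_a + self.ec50_b)


@dataclass
class ScreenTruth:
    """Ground truth for a pooled dead-vs-live screen simulation.

    The desk-scale default (1,000 genes x 4 guides + 142 non-targeting,
    depth 500) keeps every stage fast; ``full_scale()`` reproduces the
    printed TKOv3 composition exactly (70,948 targeting guides over 18,053
    genes plus 142 non-targeting controls = 71,090).
    """

    n_genes: int = 1000
    guides_per_gene: int = 4
    n_nontargeting: int = 142
    depth: float = 500.0
    dispersion: float = 0.1
    essential_fraction: float = 0.05
    essential_depletion: float = -1.0
    death_modifier_genes: dict = field(default_factory=dict)
    misassignment_rate: float = 0.0
    n_targeting: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.guides_per_gene <= 0 or self.n_nontargeting < 0:
            raise InvalidInputError("library counts must be positive")
        if self.depth <= 0:
            raise InvalidInputError("depth must be positive")
        if self.dispersion < 0:
            raise InvalidInputError("dispersion must be >= 0")
        if not 0.0 <= self.essential_fraction <= 1.0:
            raise InvalidInputError("essential_fraction must be a fraction")
        if not 0.0 <= self.misassignment_rate <= 1.0:
            raise InvalidInputError("misassignment_rate must be a fraction")
        if not all(np.isfinite(list(self.death_modifier_genes.values()) or [0.0])):
            raise InvalidInputError("death-modifier effects must be finite")

    @classmethod
    def full_scale(cls, **overrides) -> "ScreenTruth":
        kwargs = dict(
            n_genes=18053, guides_per_gene=4, n_nontargeting=142, n_targeting=70948
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class DeathKineticsTruth:
    """Ground truth for a lysis-calibrated death-kinetics time course."""

    growth_rate: float = 0.03  # per hour (~23 h doubling)
    onset_true: float = 24.0  # hours
    death_rate_true: float = 0.1  # per hour
    lf_max_true: float = 0.8
    lf0_true: float = 0.02
    initial_cells: float = 2000.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lf_max_true <= 1.0:
            raise InvalidInputError("lf_max_true must be in [0, 1]")
        if not 0.0 <= self.lf0_true <= 1.0:
            raise InvalidInputError("lf0_true must be in [0, 1]")
        if self.onset_true < 0:
            raise InvalidInputError("onset_true must be >= 0")
        if self.initial_cells <= 0:
            raise InvalidInputError("initial_cells must be positive")
        if self.noise_sd < 0 or self.death_rate_true < 0:
            raise InvalidInputError("rates and noise must be >= 0")


#: Hand-placed 8-hairpin RI centroids for five mechanism classes; pairwise
#: Euclidean separation >= ~2, i.e. >= 20 default within-class SDs.
DEFAULT_CLASS_CENTROIDS = {
    "TOP1 poison": np.array([2.5, 3.0, 1.8, 1.2, 0.6, 0.9, 1.6, 2.2]),
    "TOP2A poison": np.array([2.2, 2.6, 0.7, 1.9, 1.4, 0.5, 2.4, 1.1]),
    "spindle stabilizer": np.array([0.6, 0.4, 1.1, 2.8, 2.2, 1.7, 0.5, 0.8]),
    "spindle destabilizer": np.array([0.8, 0.5, 2.4, 0.6, 2.9, 2.1, 1.0, 0.4]),
    "EGFR inhibitor": np.array([1.0, 0.7, 0.5, 0.9, 0.6, 2.6, 1.9, 3.0]),
}


@dataclass
class SignatureTruth:
    """Ground truth for reference-set and query signature generation."""

    class_centroids: dict = field(
        default_factory=lambda: {k: v.copy() for k, v in DEFAULT_CLASS_CENTROIDS.items()}
    )
    within_class_sd: float = 0.1
    replicates_per_drug: int = 4
    roster: tuple = DEFAULT_ROSTER
    seed: int = 0

    def __post_init__(self):
        for cls, c in self.class_centroids.items():
            if np.asarray(c).shape != (len(self.roster),):
                raise InvalidInputError(
                    f"centroid for {cls!r} must have length {len(self.roster)}"
                )
        if self.within_class_sd < 0:
            raise InvalidInputError("within_class_sd must be >= 0")
        if self.replicates_per_drug < 1:
            raise InvalidInputError("replicates_per_drug must be >= 1")


# ---------------------------------------------------------------------------
# dose-response surfaces
# ---------------------------------------------------------------------------


def _fa_single(dose, ec50, hill):
    dose = np.asarray(dose, dtype=float)
    ratio = (dose / ec50) ** hill
    return ratio / (1.0 + ratio)


def _dx_single(fa, ec50, hill):
    return ec50 * (fa / (1.0 - fa)) ** (1.0 / hill)


def _fa_combo(truth: SynergyTruth, d1: float, d2: float) -> float:
    """Effect of the combination (d1, d2) under the truth's interaction mode.

    Loewe additivity solves d1/DxA(fa) + d2/DxB(fa) = 1 for fa; synergy and
    antagonism apply a potency shift (both effective doses multiplied or
    divided by 1 + strength) before the Loewe solve, giving CI < 1 and > 1
    by construction.
    """
    if truth.interaction_mode == "synergy":
        shift = 1.0 + truth.interaction_strength
    elif truth.interaction_mode == "antagonism":
        shift = 1.0 / (1.0 + truth.interaction_strength)
    else:
        shift = 1.0
    e1, e2 = d1 * shift, d2 * shift

    def loewe(fa):
        return (
            e1 / _dx_single(fa, truth.ec50_a, truth.hill_a)
            + e2 / _dx_single(fa, truth.ec50_b, truth.hill_b)
            - 1.0
        )

    lo, hi = 1e-12, 1.0 - 1e-12
    if loewe(lo) <= 0:  # dose too small to register any effect
        return 0.0
    if loewe(hi) >= 0:  # saturating dose
        return 1.0
    return float(optimize.brentq(loewe, lo, hi, xtol=1e-14))


def _check_doses(doses, name):
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise InvalidInputError(f"{name} must be non-empty")
    if np.any(doses <= 0):
        raise InvalidInputError(f"{name} must be strictly positive")
    if np.any(np.diff(doses) <= 0):
        raise InvalidInputError(f"{name} must be sorted strictly increasing")
    return doses


def gen_dose_response(
    truth: SynergyTruth,
    doses_a,
    doses_b,
    replicates: int = 3,
    control_signal: float = 1000.0,
) -> pd.DataFrame:
    """Long-format plate table for two single agents and their fixed-ratio combo.

    Combination totals are anchored on drug A's dose grid at the design
    ratio (``truth.fraction_a`` by dose).  Signals are RV x control level
    with multiplicative Gaussian noise.  Same truth/seed gives an identical
    table.
    """
    doses_a = _check_doses(doses_a, "doses_a")
    doses_b = _check_doses(doses_b, "doses_b")
    rng = np.random.default_rng(truth.seed)
    frac_a = truth.fraction_a
    rows = []

    def _emit(drug, dose_a, dose_b, rv):
        for rep in range(1, replicates + 1):
            noise = 1.0 + rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 else 1.0
            rows.append(
                {
                    "plate": "P1",
                    "well": f"{drug}_{dose_a:g}_{dose_b:g}_r{rep}",
                    "drug": drug,
                    "dose_a": dose_a,
                    "dose_b": dose_b,
                    "replicate": rep,
                    "signal": rv * control_signal * noise,
                    "role": "treated",
                }
            )

    for d in doses_a:
        _emit("A", float(d), 0.0, 1.0 - _fa_single(d, truth.ec50_a, truth.hill_a))
    for d in doses_b:
        _emit("B", 0.0, float(d), 1.0 - _fa_single(d, truth.ec50_b, truth.hill_b))
    for d in doses_a:
        total = float(d) / frac_a
        d1, d2 = frac_a * total, (1.0 - frac_a) * total
        _emit("A+B", d1, d2, 1.0 - _fa_combo(truth, d1, d2))
    for rep in range(1, replicates + 1):
        noise = 1.0 + rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 else 1.0
        rows.append(
            {
                "plate": "P1",
                "well": f"ctrl_r{rep}",
                "drug": "",
                "dose_a": 0.0,
                "dose_b": 0.0,
                "replicate": rep,
                "signal": control_signal * noise,
                "role": "control",
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["fraction_a"] = frac_a
    table.attrs["seed"] = truth.seed
    return table


# ---------------------------------------------------------------------------
# CRISPR library and counts
# ---------------------------------------------------------------------------


def gen_crispr_library(truth: ScreenTruth) -> pd.DataFrame:
    """Library annotation: one row per guide (sgRNA, gene, nontargeting).

    ``n_targeting`` guides are distributed as evenly as possible over
    ``n_genes`` (full scale: 16,789 genes x 4 + 1,264 x 3 = 70,948, plus 142
    non-targeting controls = 71,090 records).
    """
    n_targeting = (
        truth.n_targeting
        if truth.n_targeting is not None
        else truth.n_genes * truth.guides_per_gene
    )
    base, extra = divmod(n_targeting, truth.n_genes)
    if base == 0:
        raise InvalidInputError("fewer targeting guides than genes")
    records = []
    width = len(str(truth.n_genes))
    for g in range(truth.n_genes):
        gene = f"GENE{g + 1:0{width}d}"
        n_g = base + (1 if g < extra else 0)
        for i in range(n_g):
            records.append((f"{gene}_sg{i + 1}", gene, False))
    for i in range(truth.n_nontargeting):
        records.append((f"NT_sg{i + 1:03d}", NONTARGETING, True))
    lib = pd.DataFrame(records, columns=["sgRNA", "gene", "nontargeting"])
    return lib.set_index("sgRNA")


@dataclass
class SampleSpec:
    name: str
    role: str
    treatment: str = ""
    replicate: int = 1


def default_screen_samples(treatments=("drug", "combo")) -> list[SampleSpec]:
    """T0 and untreated in duplicate plus dead/live duplicates per treatment."""
    samples = [
        SampleSpec("T0_r1", "T0", "", 1),
        SampleSpec("T0_r2", "T0", "", 2),
        SampleSpec("untreated_r1", "untreated", "", 1),
        SampleSpec("untreated_r2", "untreated", "", 2),
    ]
    for t in treatments:
        for role in ("dead", "live"):
            for rep in (1, 2):
                samples.append(SampleSpec(f"{t}_{role}_r{rep}", role, t, rep))
    return samples


def gen_screen_counts(
    library: pd.DataFrame,
    truth: ScreenTruth,
    samples: list[SampleSpec] | None = None,
) -> GuideCountMatrix:
    """Negative-binomial counts around planted expected abundances.

    Essential genes (the first ``essential_fraction`` of genes not used as
    death modifiers) are depleted by ``essential_depletion`` log2 units in
    every post-T0 sample; death-modifier gene g with effect D is shifted
    +D/2 in dead and -D/2 in live fractions, so its dead-vs-live guide L2FC
    equals D in expectation.  ``misassignment_rate`` mixes the dead/live
    expectations to emulate imperfect sorting.  NB variance is
    mu + dispersion * mu^2; dispersion 0 degenerates to the expectation.
    """
    if samples is None:
        samples = default_screen_samples()
    for s in samples:
        if s.role not in ("T0", "untreated", "dead", "live"):
            raise InvalidInputError(f"unknown sample role {s.role!r} for {s.name!r}")
    genes = [g for g in library["gene"].unique() if g != NONTARGETING]
    modifiers = dict(truth.death_modifier_genes)
    n_essential = int(round(truth.essential_fraction * len(genes)))
    essential = [g for g in genes if g not in modifiers][:n_essential]
    ess_set = set(essential)

    gene_col = library["gene"].to_numpy()
    ess_mask = np.isin(gene_col, list(ess_set))
    mod_effect = np.array([modifiers.get(g, 0.0) for g in gene_col])

    rng = np.random.default_rng(truth.seed)
    counts = {}
    for s in samples:
        shift = np.zeros(len(library))
        if s.role != "T0":
            shift = shift + ess_mask * truth.essential_depletion
        if s.role == "dead":
            shift = shift + mod_effect / 2.0
        elif s.role == "live":
            shift = shift - mod_effect / 2.0
        mu = truth.depth * 2.0 ** shift
        if s.role in ("dead", "live") and truth.misassignment_rate > 0:
            other = shift - mod_effect if s.role == "dead" else shift + mod_effect
            mu_other = truth.depth * 2.0 ** other
            rho = truth.misassignment_rate
            mu = (1.0 - rho) * mu + rho * mu_other
        if truth.dispersion == 0:
            counts[s.name] = np.rint(mu).astype(np.int64)
        else:
            n_param = 1.0 / truth.dispersion
            p_param = n_param / (n_param + mu)
            counts[s.name] = rng.negative_binomial(n_param, p_param).astype(np.int64)
    counts_df = pd.DataFrame(counts, index=library.index)
    samples_df = pd.DataFrame(
        {
            "role": [s.role for s in samples],
            "treatment": [s.treatment for s in samples],
            "replicate": [s.replicate for s in samples],
        },
        index=pd.Index([s.name for s in samples], name="sample"),
    )
    return GuideCountMatrix(counts=counts_df, guides=library.copy(), samples=samples_df)


def planted_essentials(library: pd.DataFrame, truth: ScreenTruth) -> list[str]:
    """The essential-gene list implied by the truth (for KS QC tests)."""
    genes = [g for g in library["gene"].unique() if g != NONTARGETING]
    modifiers = set(truth.death_modifier_genes)
    n_essential = int(round(truth.essential_fraction * len(genes)))
    return [g for g in genes if g not in modifiers][:n_essential]


# ---------------------------------------------------------------------------
# FLICK time courses
# ---------------------------------------------------------------------------


def _led_curve(t, lf0, lf_max, onset, rate):
    lag = np.clip(np.asarray(t, dtype=float) - onset, 0.0, None)
    return lf0 + (lf_max - lf0) * (1.0 - np.exp(-rate * lag))


def gen_flick_plate(
    truth: DeathKineticsTruth,
    timepoints,
    conditions=("treated",),
    signal_per_cell: float = 1.0,
) -> dict[str, PopulationTimecourse]:
    """Per-condition dead-signal time courses with lysis anchors.

    The total population grows exponentially at ``growth_rate``; the lethal
    fraction follows the lag-exponential death curve of the truth.  A
    condition named ``"untreated"`` stays at the baseline lethal fraction.
    ``conditions`` entries are either labels or ``(label, overrides)`` pairs
    overriding dose / lf_max / onset / death_rate / growth_rate / lf0.
    """
    t = np.asarray(timepoints, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise InvalidInputError("need >= 2 timepoints")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("timepoints must be sorted strictly increasing")
    rng = np.random.default_rng(truth.seed)
    out = {}
    for cond in conditions:
        label, over = (cond, {}) if isinstance(cond, str) else (cond[0], dict(cond[1]))
        growth = over.get("growth_rate", truth.growth_rate)
        lf0 = over.get("lf0", truth.lf0_true)
        if label == "untreated":
            lf_max, onset, rate = lf0, 0.0, 0.0
        else:
            lf_max = over.get("lf_max", truth.lf_max_true)
            onset = over.get("onset", truth.onset_true)
            rate = over.get("death_rate", truth.death_rate_true)
        total = truth.initial_cells * np.exp(growth * (t - t[0]))
        lf = (
            np.full_like(t, lf0)
            if rate == 0 or lf_max <= lf0
            else _led_curve(t, lf0, lf_max, onset, rate)
        )
        dead = total * lf

        def _noisy(x):
            if truth.noise_sd == 0:
                return x
            return x * (1.0 + rng.normal(0.0, truth.noise_sd, size=np.shape(x)))

        out[label] = PopulationTimecourse(
            condition=label,
            dose=float(over.get("dose", 0.0)),
            timepoints=t,
            dead_signal=np.maximum(_noisy(dead * signal_per_cell), 0.0),
            t0_lysis_signal=float(
                max(_noisy(truth.initial_cells * signal_per_cell), 1e-9)
            ),
            end_lysis_signal=float(max(_noisy(total[-1] * signal_per_cell), 1e-9)),
        )
    return out


def gen_flick_dose_series(
    synergy: SynergyTruth,
    kinetics: DeathKineticsTruth,
    doses_a,
    doses_b,
    timepoints,
) -> dict[str, dict]:
    """Death time courses across a dose grid, for LF-based CI analysis.

    The asymptotic lethal fraction at each dose equals the fraction affected
    of the interaction surface used by :func:`gen_dose_response`, so the
    LF-based and RV-based combination indices agree on matched truth.
    Returns ``{series: {"doses": array, "timecourses": [...]}}`` for series
    "A", "B" (single-agent dose) and "A+B" (total dose).
    """
    doses_a = _check_doses(doses_a, "doses_a")
    doses_b = _check_doses(doses_b, "doses_b")
    frac_a = synergy.fraction_a
    series: dict[str, dict] = {}

    def _conditions(doses, fa_of):
        conds = []
        for d in doses:
            conds.append((f"d{d:g}", {"dose": float(d), "lf_max": float(fa_of(d))}))
        return conds

    fa_a = lambda d: _fa_single(d, synergy.ec50_a, synergy.hill_a)
    fa_b = lambda d: _fa_single(d, synergy.ec50_b, synergy.hill_b)
    fa_c = lambda total: _fa_combo(synergy, frac_a * total, (1.0 - frac_a) * total)
    totals = doses_a / frac_a
    for name, doses, fa_of in (
        ("A", doses_a, fa_a),
        ("B", doses_b, fa_b),
        ("A+B", totals, fa_c),
    ):
        plates = gen_flick_plate(kinetics, timepoints, _conditions(doses, fa_of))
        series[name] = {
            "doses": np.asarray(doses, dtype=float),
            "timecourses": [plates[f"d{d:g}"] for d in doses],
        }
    series["fraction_a"] = frac_a
    return series


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------


def gen_signature_data(
    truth: SignatureTruth, query_spec: dict | None = None
) -> tuple[ReferenceSet, list[Signature]]:
    """Reference set of noisy class signatures plus query signatures.

    ``query_spec`` maps query name -> class name (draw near that centroid),
    ``"novel"`` (a vector far from every centroid), or a dict
    ``{"class": name, "sd": s}`` controlling the query's own noise (sd 0
    gives the exact centroid).
    """
    rng = np.random.default_rng(truth.seed)
    signatures, labels = [], []
    for cls in sorted(truth.class_centroids):
        centroid = np.asarray(truth.class_centroids[cls], dtype=float)
        for rep in range(1, truth.replicates_per_drug + 1):
            ri = centroid + rng.normal(0.0, truth.within_class_sd, size=len(centroid))
            signatures.append(
                Signature(drug=f"{cls} ref{rep}", ri=np.clip(ri, 0.0, None), roster=truth.roster)
            )
            labels.append(cls)
    ref = ReferenceSet(signatures=signatures, labels=labels)
    queries = []
    for name, spec in (query_spec or {}).items():
        if isinstance(spec, dict):
            cls, sd = spec["class"], float(spec.get("sd", truth.within_class_sd))
        else:
            cls, sd = spec, truth.within_class_sd
        if cls == "novel":
            # far from every centroid: distance >= ~14 vs centroid entries <= 3
            ri = np.full(len(truth.roster), 8.0)
            if sd > 0:
                ri = ri + rng.normal(0.0, sd, size=len(ri))
        elif cls in truth.class_centroids:
            centroid = np.asarray(truth.class_centroids[cls], dtype=float)
            ri = centroid.copy()
            if sd > 0:
                ri = ri + rng.normal(0.0, sd, size=len(ri))
        else:
            raise InvalidInputError(f"unknown signature class {cls!r}")
        queries.append(Signature(drug=name, ri=np.clip(ri, 0.0, None), roster=truth.roster))
    return ref, queries
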