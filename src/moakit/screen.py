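"""Dead-vs-live pooled CRISPR screen scoring.

Counts are normalized by median-of-ratios size factors, turned into
pseudocounted guide-level log2 fold changes per replicate, averaged, and
aggregated to gene-level fold changes (FC).  Non-targeting control guides are
randomly chunked into pseudo-genes of four guides; their FC distribution
supplies the mean/SD used to z-score every gene (zL2FC) and the guide pool
for a bootstrap null from which two-sided empirical p-values are drawn,
followed by Benjamini-Hochberg FDR.  Positive zL2FC in the dead-vs-live
comparison reads as an increased death rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    AlignmentError,
    DegenerateNullError,
    InsufficientControlsError,
    InvalidInputError,
    NormalizationError,
)

#: Gene label reserved for non-targeting control guides.
NONTARGETING = "NONTARGETING"

VALID_ROLES = ("T0", "untreated", "dead", "live")


@dataclass
class GuideCountMatrix:
    """sgRNA x sample count matrix with library and sample annotations.

    ``counts``: DataFrame indexed by guide id, one integer column per sample.
    ``guides``: DataFrame indexed by guide id with columns ``gene`` and
    ``nontargeting`` (bool).  ``samples``: DataFrame indexed by sample name
    with columns ``role`` (T0/untreated/dead/live), ``treatment``,
    ``replicate``.
    """

    counts: pd.DataFrame
    guides: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise InvalidInputError(f"duplicate guide ids: {dups[:5]}")
        if not self.counts.index.equals(self.guides.index):
            raise InvalidInputError("counts and guide annotation indices differ")
        missing = [s for s in self.samples.index if s not in self.counts.columns]
        if missing:
            raise InvalidInputError(f"declared samples absent from counts: {missing}")
        bad = set(self.samples["role"]) - set(VALID_ROLES)
        if bad:
            raise InvalidInputError(f"unknown sample roles: {sorted(bad)}")
        if (self.counts.to_numpy() < 0).any():
            raise InvalidInputError("counts must be non-negative")

    @property
    def nontargeting_ids(self) -> list[str]:
        return self.guides.index[self.guides["nontargeting"]].tolist()

    def samples_for(self, role: str, treatment: str | None = None) -> pd.DataFrame:
        sub = self.samples[self.samples["role"] == role]
        if treatment is not None and role in ("dead", "live"):
            sub = sub[sub["treatment"] == treatment]
        return sub.sort_values("replicate")

    @property
    def treatments(self) -> list[str]:
        mask = self.samples["role"].isin(["dead", "live"])
        return sorted(self.samples.loc[mask, "treatment"].unique())


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample the factor is the median over all-positive guides of
    count / geometric-mean-across-samples.
    """
    values = counts.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise NormalizationError("no guide has positive counts in every sample")
    positive = values[all_positive]
    gm = np.exp(np.log(positive).mean(axis=1, keepdims=True))
    factors = np.median(positive / gm, axis=0)
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return pd.Series(factors, index=counts.columns, name="size_factor")


def guide_l2fc(
    gcm: GuideCountMatrix,
    numerator_role: str,
    denominator_role: str,
    treatment: str | None = None,
    pseudocount: float = 0.5,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-replicate, then averaged, guide-level log2 fold changes.

    l2fc = log2((count_num/factor_num + c) / (count_den/factor_den + c)),
    paired by replicate id.  Returns a frame indexed by guide with one
    ``l2fc_rep*`` column per replicate pair, the averaged ``l2fc``, and the
    guide annotation.
    """
    if factors is None:
        factors = size_factors(gcm.counts)
    num = gcm.samples_for(numerator_role, treatment)
    den = gcm.samples_for(denominator_role, treatment)
    if num.empty or den.empty:
        raise InvalidInputError(
            f"no samples for comparison {numerator_role} vs {denominator_role}"
            + (f" (treatment {treatment!r})" if treatment else "")
        )
    shared = sorted(set(num["replicate"]) & set(den["replicate"]))
    if not shared:
        raise InvalidInputError("numerator and denominator share no replicate ids")
    out = pd.DataFrame(index=gcm.counts.index)
    rep_cols = []
    for rep in shared:
        ns = num.index[num["replicate"] == rep][0]
        ds = den.index[den["replicate"] == rep][0]
        n_norm = gcm.counts[ns].to_numpy(dtype=float) / factors[ns]
        d_norm = gcm.counts[ds].to_numpy(dtype=float) / factors[ds]
        col = f"l2fc_rep{rep}"
        out[col] = np.log2((n_norm + pseudocount) / (d_norm + pseudocount))
        rep_cols.append(col)
    out["l2fc"] = out[rep_cols].mean(axis=1)
    out["gene"] = gcm.guides["gene"]
    out["nontargeting"] = gcm.guides["nontargeting"]
    return out


def replicate_correlation(l2fc_table: pd.DataFrame) -> float:
    """Pearson r between the first two replicate l2fc columns (QC); NaN if < 2."""
    rep_cols = [c for c in l2fc_table.columns if c.startswith("l2fc_rep")]
    if len(rep_cols) < 2:
        return float("nan")
    a = l2fc_table[rep_cols[0]].to_numpy()
    b = l2fc_table[rep_cols[1]].to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class PseudoGeneAssignment:
    """Random partition of non-targeting guides into sets of four."""

    sets: dict[str, list[str]]
    reused_ids: list[str]
    seed: int

    def __len__(self):
        return len(self.sets)


def assign_pseudogenes(
    nontargeting_ids, set_size: int = 4, seed: int = 0
) -> PseudoGeneAssignment:
    """Shuffle non-targeting guide ids and chunk them into pseudo-genes.

    When the pool size is not divisible by ``set_size`` the remainder set is
    completed by seeded resampling of already-used ids (flagged), so 142
    controls yield exactly 36 sets of four.
    """
    ids = list(nontargeting_ids)
    if len(ids) < set_size:
        raise InsufficientControlsError(
            f"need >= {set_size} non-targeting guides, got {len(ids)}"
        )
    rng = np.random.default_rng(seed)
    shuffled = [ids[i] for i in rng.permutation(len(ids))]
    n_sets = math.ceil(len(ids) / set_size)
    sets: dict[str, list[str]] = {}
    reused: list[str] = []
    for i in range(n_sets):
        chunk = shuffled[i * set_size : (i + 1) * set_size]
        deficit = set_size - len(chunk)
        if deficit:
            used = [g for g in shuffled if g not in chunk]
            extra = [used[j] for j in rng.choice(len(used), size=deficit, replace=False)]
            reused.extend(extra)
            chunk = chunk + extra
        sets[f"PSEUDO_{i + 1:03d}"] = chunk
    return PseudoGeneAssignment(sets=sets, reused_ids=reused, seed=seed)


def gene_scores(
    l2fc_table: pd.DataFrame, pseudo: PseudoGeneAssignment | None = None
) -> pd.DataFrame:
    """Gene-level FC = arithmetic mean of the gene's averaged guide l2fc.

    Pseudo-genes are scored through the identical code path; rows are flagged
    by ``is_pseudo``.  Returns a frame indexed by gene with ``fc`` and
    ``n_guides``.
    """
    targeting = l2fc_table[~l2fc_table["nontargeting"]]
    grouped = targeting.groupby("gene")["l2fc"]
    real = pd.DataFrame({"fc": grouped.mean(), "n_guides": grouped.size().astype(int)})
    real["is_pseudo"] = False
    frames = [real]
    if pseudo is not None:
        rows = {}
        for name, members in pseudo.sets.items():
            vals = l2fc_table.loc[members, "l2fc"]
            rows[name] = (float(vals.mean()), len(members))
        pseudo_df = pd.DataFrame.from_dict(rows, orient="index", columns=["fc", "n_guides"])
        pseudo_df["n_guides"] = pseudo_df["n_guides"].astype(int)
        pseudo_df["is_pseudo"] = True
        frames.append(pseudo_df)
    out = pd.concat(frames)
    out.index.name = "gene"
    return out


def zscore_genes(gene_fc: pd.Series, pseudo_fc: pd.Series) -> pd.Series:
    """z-score gene FCs against the pseudo-gene mean and sample SD (ddof=1)."""
    pseudo_fc = pd.Series(pseudo_fc).astype(float)
    if len(pseudo_fc) < 2:
        raise InsufficientControlsError("need >= 2 pseudo-genes for z-scoring")
    mu = float(pseudo_fc.mean())
    sd = float(pseudo_fc.std(ddof=1))
    if sd == 0:
        raise DegenerateNullError("pseudo-gene FCs have zero spread")
    return (gene_fc - mu) / sd


def bootstrap_pvalues(
    gene_table: pd.DataFrame,
    guide_pool: np.ndarray,
    pseudo_mean: float,
    pseudo_sd: float,
    B: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Two-sided empirical p-values from a guide-resampling bootstrap null.

    For each gene size n, B pseudo-FCs are built by resampling n guide-level
    l2fc values (with replacement) from the non-targeting pool, z-scored with
    the same pseudo-gene statistics, and compared with the gene's |z|:
    p = (1 + #{|z_null| >= |z|}) / (B + 1), so the attainable minimum is
    1/(B+1).
    """
    pool = np.asarray(guide_pool, dtype=float)
    if pool.size == 0:
        raise InsufficientControlsError("empty guide pool for bootstrap null")
    if pseudo_sd <= 0:
        raise DegenerateNullError("pseudo-gene SD must be positive")
    rng = np.random.default_rng(seed)
    z = (gene_table["fc"].to_numpy(dtype=float) - pseudo_mean) / pseudo_sd
    n_guides = gene_table["n_guides"].to_numpy(dtype=int)
    p = np.empty(len(gene_table), dtype=float)
    for n in np.unique(n_guides):
        draws = rng.choice(pool, size=(B, int(n)), replace=True).mean(axis=1)
        z_null = np.sort(np.abs((draws - pseudo_mean) / pseudo_sd))
        mask = n_guides == n
        # count of |z_null| >= |z| via sorted search
        ge = B - np.searchsorted(z_null, np.abs(z[mask]), side="left")
        p[mask] = (1.0 + ge) / (B + 1.0)
    return pd.Series(p, index=gene_table.index, name="p_empirical")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs propagate with a warning."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p[np.isfinite(p)] < 0) | (p[np.isfinite(p)] > 1)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    finite = np.isfinite(p)
    if not finite.all():
        warnings.warn("NaN p-values propagated through BH correction", stacklevel=2)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


@dataclass
class HitCalls:
    """Per-treatment hit sets at an FDR threshold plus cross-treatment stats."""

    hits: dict[str, dict[str, set]]
    intersection: set
    unique: dict[str, set]
    r_squared: float
    fdr_threshold: float


def call_hits(gene_tables: dict[str, pd.DataFrame], fdr_threshold: float = 0.1) -> HitCalls:
    """Call FDR hits per treatment, split by zL2FC sign, and compare treatments.

    Positive zL2FC = increased death rate, negative = increased survival.
    With two treatments, R^2 of their zL2FC is computed over the union of
    hit genes.
    """
    names = list(gene_tables)
    universes = [set(t.index) for t in gene_tables.values()]
    if any(u != universes[0] for u in universes[1:]):
        raise AlignmentError("gene tables do not share a gene universe")
    hits: dict[str, dict[str, set]] = {}
    for name, table in gene_tables.items():
        sig = table[table["fdr"] < fdr_threshold]
        hits[name] = {
            "positive": set(sig.index[sig["zl2fc"] > 0]),
            "negative": set(sig.index[sig["zl2fc"] < 0]),
        }
    all_hits = {name: h["positive"] | h["negative"] for name, h in hits.items()}
    intersection = set.intersection(*all_hits.values()) if all_hits else set()
    unique = {
        name: all_hits[name] - set.union(*(v for k, v in all_hits.items() if k != name))
        for name in names
    } if len(names) > 1 else {names[0]: all_hits[names[0]]} if names else {}
    r_squared = float("nan")
    if len(names) == 2:
        union = sorted(all_hits[names[0]] | all_hits[names[1]])
        if len(union) >= 2:
            z1 = gene_tables[names[0]].loc[union, "zl2fc"].to_numpy(dtype=float)
            z2 = gene_tables[names[1]].loc[union, "zl2fc"].to_numpy(dtype=float)
            if np.std(z1) > 0 and np.std(z2) > 0:
                r_squared = float(np.corrcoef(z1, z2)[0, 1] ** 2)
            elif np.allclose(z1, z2):
                r_squared = 1.0
    return HitCalls(
        hits=hits,
        intersection=intersection,
        unique=unique,
        r_squared=r_squared,
        fdr_threshold=fdr_threshold,
    )


@dataclass
class KSEssentialQC:
    d_statistic: float
    p_value: float
    essentials_depleted: bool
    n_essential: int


def ks_essential_qc(gene_z: pd.Series, essential_genes) -> KSEssentialQC:
    """Two-sample KS test of essential vs non-essential zL2FC distributions.

    Run on the untreated-vs-T0 comparison as screen QC; a healthy screen
    shows essentials shifted toward depletion.
    """
    essential = set(essential_genes) & set(gene_z.index)
    if not essential:
        raise InvalidInputError("essential gene list does not intersect the gene universe")
    if len(essential) < 10:
        warnings.warn(
            f"only {len(essential)} essential genes present; KS QC is underpowered",
            stacklevel=2,
        )
    ess = gene_z.loc[sorted(essential)].to_numpy(dtype=float)
    rest = gene_z.drop(index=sorted(essential)).to_numpy(dtype=float)
    res = stats.ks_2samp(ess, rest, method="asymp")
    return KSEssentialQC(
        d_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        essentials_depleted=bool(ess.mean() < rest.mean()),
        n_essential=len(essential),
    )


@dataclass
class ScreenResults:
    """Scored screen: one gene table per comparison plus shared QC objects."""

    tables: dict[str, pd.DataFrame]
    size_factors: pd.Series
    pseudo_assignment: PseudoGeneAssignment
    replicate_qc: dict[str, float] = field(default_factory=dict)

    def gene_table(self, key: str, include_pseudo: bool = False) -> pd.DataFrame:
        t = self.tables[key]
        return t if include_pseudo else t[~t["is_pseudo"]]

    def summary(self) -> str:
        lines = ["Screen scoring summary", "======================"]
        for key, table in self.tables.items():
            real = table[~table["is_pseudo"]]
            n_sig = int((real["fdr"] < 0.1).sum())
            lines.append(
                f"{key}: {len(real)} genes, {int(table['is_pseudo'].sum())} pseudo-genes, "
                f"{n_sig} genes at FDR < 0.1 "
                f"(replicate r = {self.replicate_qc.get(key, float('nan')):.3f})"
            )
        return "\n".join(lines)


def score_screen(
    gcm: GuideCountMatrix,
    comparisons: list[tuple[str, str, str | None]] | None = None,
    B: int = 1000,
    seed: int = 0,
    pseudocount: float = 0.5,
    set_size: int = 4,
    pool: str = "nontargeting",
) -> ScreenResults:
    """Run the full scoring chain for each comparison.

    ``comparisons`` is a list of (numerator_role, denominator_role,
    treatment); the default scores dead-vs-live for every treatment plus
    untreated-vs-T0.  ``pool`` selects the bootstrap guide pool
    ("nontargeting" or "all").
    """
    if pool not in ("nontargeting", "all"):
        raise InvalidInputError("pool must be 'nontargeting' or 'all'")
    if comparisons is None:
        comparisons = [("dead", "live", t) for t in gcm.treatments]
        comparisons.append(("untreated", "T0", None))
    factors = size_factors(gcm.counts)
    pseudo = assign_pseudogenes(gcm.nontargeting_ids, set_size=set_size, seed=seed)
    tables: dict[str, pd.DataFrame] = {}
    replicate_qc: dict[str, float] = {}
    for i, (num, den, treatment) in enumerate(comparisons):
        key = f"{num}_vs_{den}" + (f"_{treatment}" if treatment else "")
        l2fc = guide_l2fc(gcm, num, den, treatment, pseudocount=pseudocount, factors=factors)
        replicate_qc[key] = replicate_correlation(l2fc)
        genes = gene_scores(l2fc, pseudo)
        pseudo_fc = genes.loc[genes["is_pseudo"], "fc"]
        genes["zl2fc"] = zscore_genes(genes["fc"], pseudo_fc)
        if pool == "nontargeting":
            guide_pool = l2fc.loc[l2fc["nontargeting"], "l2fc"].to_numpy()
        else:
            guide_pool = l2fc["l2fc"].to_numpy()
        genes["p_empirical"] = bootstrap_pvalues(
            genes,
            guide_pool,
            float(pseudo_fc.mean()),
            float(pseudo_fc.std(ddof=1)),
            B=B,
            seed=seed + 7919 * (i + 1),
        )
        real = ~genes["is_pseudo"]
        genes["fdr"] = np.nan
        genes.loc[real, "fdr"] = bh_fdr(genes.loc[real, "p_empirical"].to_numpy())
        genes["comparison"] = f"{num}_vs_{den}"
        genes["treatment"] = treatment if treatment else ""
        tables[key] = genes
    return ScreenResults(
        tables=tables,
        size_factors=factors,
        pseudo_assignment=pseudo,
        replicate_qc=replicate_qc,
    )
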