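"""Allele classification and decade-to-decade cohort comparison.

Classification follows the conservation-monitoring conventions for
livestock STR panels: an allele is *rare* when its cohort frequency is
strictly below 0.05, *common* at or above a configurable threshold
(default 0.25, the regime of the modal alleles at most equine loci), and
*unique* (private) when it is observed in the focal cohort but in none
of the supplied reference populations.  No reference tables are bundled;
unique-allele detection is only as good as the references the user
provides.

Temporal comparison builds, per locus, the alleles x {cohort_a,
cohort_b} contingency table of allele *copy* counts and tests it with a
Pearson chi-square on k-1 degrees of freedom over the allele union.
Copy counts within a diploid are not fully independent, so an
individual-level permutation test (cohort labels shuffled over animals,
Pearson statistic recomputed) is offered and is the recommended headline
p-value; chi-square remains the fast default.  A per-allele 2x2 Fisher
exact collapse (focal allele vs rest) is also available.  Raw p-values
are reported alongside Holm-adjusted values across the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diversity import AlleleFrequencyTable, allele_frequencies, count_genotypes
from .model import GenotypeTable

__all__ = [
    "AlleleClassification",
    "LocusComparison",
    "TemporalComparison",
    "AlleleTrajectory",
    "classify_alleles",
    "compare_cohorts",
    "frequency_trajectory",
    "comparison_to_tsv",
    "classification_to_tsv",
]


# ---------------------------------------------------------------------------
# Classification


@dataclass(frozen=True)
class AlleleClassification:
    """Common / rare / unique allele sets (with frequencies) for one locus."""

    cohort: str
    locus: str
    rare_threshold: float
    common_threshold: float
    common: dict[str, float]
    rare: dict[str, float]
    intermediate: dict[str, float]
    unique: dict[str, float]


def classify_alleles(
    freqs: AlleleFrequencyTable,
    rare_threshold: float = 0.05,
    common_threshold: float = 0.25,
    references: Sequence[AlleleFrequencyTable] = (),
) -> AlleleClassification:
    """Partition observed alleles into common / intermediate / rare sets.

    Rare means ``0 < p < rare_threshold`` (strict: an allele at exactly
    the threshold is not rare); common means ``p >= common_threshold``.
    With ``common_threshold >= rare_threshold`` the three sets partition
    the observed alleles.  ``unique`` holds alleles absent from every
    reference table (empty references => no allele is called unique).
    """
    for thr, name in ((rare_threshold, "rare_threshold"),
                      (common_threshold, "common_threshold")):
        if not (0.0 < thr < 1.0):
            raise ValueError(f"{name} must be in (0, 1), got {thr}")
    for ref in references:
        if ref.locus != freqs.locus:
            raise ValueError(
                f"reference table is for locus {ref.locus!r}, focal is {freqs.locus!r}"
            )
    common, rare, inter = {}, {}, {}
    for a, p in freqs.freqs.items():
        if p >= common_threshold:
            common[a] = p
        elif p < rare_threshold:
            rare[a] = p
        else:
            inter[a] = p
    ref_alleles: set[str] = set()
    for ref in references:
        ref_alleles.update(a for a, c in ref.counts.items() if c > 0)
    unique = (
        {a: p for a, p in freqs.freqs.items() if a not in ref_alleles}
        if references else {}
    )
    return AlleleClassification(
        cohort=freqs.cohort,
        locus=freqs.locus,
        rare_threshold=rare_threshold,
        common_threshold=common_threshold,
        common=common,
        rare=rare,
        intermediate=inter,
        unique=unique,
    )


# ---------------------------------------------------------------------------
# Cohort comparison


@dataclass(frozen=True)
class LocusComparison:
    """Per-locus allele-pool change and test results between two cohorts."""

    locus: str
    gained: dict[str, float]          # alleles in b but not a, with freq in b
    lost: dict[str, float]            # alleles in a but not b, with freq in a
    shared_ratio: dict[str, float]    # p_b / p_a for alleles in both
    freqs_a: dict[str, float]
    freqs_b: dict[str, float]
    statistic: float
    df: int
    p_value: float
    p_holm: float = float("nan")      # filled across loci by compare_cohorts
    per_allele_p: dict[str, float] = field(default_factory=dict)
    n_genotypes_a: int = 0
    n_genotypes_b: int = 0
    genotype_statistic: float = float("nan")
    genotype_p_value: float = float("nan")


@dataclass(frozen=True)
class TemporalComparison:
    cohort_a: str
    cohort_b: str
    test: str
    per_locus: tuple[LocusComparison, ...]

    def locus(self, name: str) -> LocusComparison:
        for lc in self.per_locus:
            if lc.locus == name:
                return lc
        raise KeyError(name)


def pearson_chi2(observed: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square statistic and df for a k x 2 copy-count table.

    Degrees of freedom are k-1 over the allele union.  Cells whose
    expected count is zero (possible only when a whole row or column is
    empty) contribute nothing to the statistic.
    """
    observed = np.asarray(observed, dtype=float)
    total = observed.sum()
    if total == 0:
        return 0.0, max(observed.shape[0] - 1, 0)
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    return float(terms.sum()), observed.shape[0] - 1


def _copy_count_matrix(
    table: GenotypeTable, cohort_a: str, cohort_b: str, locus: str
) -> tuple[list[str], np.ndarray]:
    fa = allele_frequencies(table, cohort_a, locus)
    fb = allele_frequencies(table, cohort_b, locus)
    alleles = sorted(set(fa.counts) | set(fb.counts))
    obs = np.array(
        [[fa.counts.get(a, 0), fb.counts.get(a, 0)] for a in alleles], dtype=float
    )
    return alleles, obs


def _individual_allele_counts(
    table: GenotypeTable, cohorts: tuple[str, str], locus: str, alleles: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """(individuals x alleles) copy matrix and boolean cohort-a mask."""
    idx = {a: i for i, a in enumerate(alleles)}
    rows, in_a = [], []
    i_locus = table.locus_index(locus)
    for rec in table.samples:
        if rec.cohort not in cohorts:
            continue
        g = rec.genotypes[i_locus]
        if g.is_missing:
            continue
        row = np.zeros(len(alleles), dtype=np.int64)
        for al in g.alleles():
            row[idx[al]] += 1
        rows.append(row)
        in_a.append(rec.cohort == cohorts[0])
    return np.array(rows), np.array(in_a, dtype=bool)


def _permutation_pvalue(
    counts: np.ndarray, in_a: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Label-shuffle permutation p for the Pearson statistic.

    ``p = (1 + #{perm >= obs}) / (1 + n_perm)`` — never exactly zero.
    """
    col_a = counts[in_a].sum(axis=0).astype(float)
    col_tot = counts.sum(axis=0).astype(float)
    obs_stat, _ = pearson_chi2(np.column_stack([col_a, col_tot - col_a]))
    n = counts.shape[0]
    n_a = int(in_a.sum())
    # With no missing data the margins are fixed under label shuffles, so the
    # Pearson statistic is a function of cohort-a's copy vector alone; with
    # missing data margins vary per permutation and are recomputed.
    exceed = 0
    block = 2048
    done = 0
    while done < n_perm:
        m = min(block, n_perm - done)
        order = np.argsort(rng.random((m, n)), axis=1)[:, :n_a]
        perm_a = counts[order].sum(axis=1).astype(float)  # m x k
        perm_b = col_tot[None, :] - perm_a
        row_tot = col_tot[None, :]
        na_tot = perm_a.sum(axis=1, keepdims=True)
        nb_tot = perm_b.sum(axis=1, keepdims=True)
        grand = na_tot + nb_tot
        ea = row_tot * na_tot / grand
        eb = row_tot * nb_tot / grand
        with np.errstate(divide="ignore", invalid="ignore"):
            stats_ = np.where(ea > 0, (perm_a - ea) ** 2 / ea, 0.0).sum(axis=1)
            stats_ += np.where(eb > 0, (perm_b - eb) ** 2 / eb, 0.0).sum(axis=1)
        exceed += int((stats_ >= obs_stat - 1e-12).sum())
        done += m
    return obs_stat, (1 + exceed) / (1 + n_perm)


def _genotype_contingency(
    table: GenotypeTable, cohort_a: str, cohort_b: str, locus: str
) -> np.ndarray:
    i_locus = table.locus_index(locus)
    cats: dict[tuple[str, str], list[int]] = {}
    for rec in table.samples:
        if rec.cohort not in (cohort_a, cohort_b):
            continue
        g = rec.genotypes[i_locus]
        if g.is_missing:
            continue
        key = (g.allele_a, g.allele_b)
        cats.setdefault(key, [0, 0])[0 if rec.cohort == cohort_a else 1] += 1
    return np.array([cats[k] for k in sorted(cats)], dtype=float)


def compare_cohorts(
    table: GenotypeTable,
    cohort_a: str,
    cohort_b: str,
    test: str = "chi2",
    n_perm: int = 10000,
    seed: Optional[int] = None,
) -> TemporalComparison:
    """Allele-pool inventory and frequency-shift tests between two cohorts.

    Per locus: gained alleles (present in *cohort_b* only), lost alleles
    (present in *cohort_a* only), frequency ratios ``p_b/p_a`` for shared
    alleles, the allele copy-count test, and the genotype-category test
    with the distinct-genotype counts.

    ``test`` is one of ``chi2`` (Pearson, df = k-1), ``fisher``
    (per-allele 2x2 exact collapses; the locus p is the Bonferroni
    minimum), or ``permutation`` (cohort labels shuffled over animals,
    ``p = (1 + #{perm >= obs}) / (1 + n_perm)``).  Holm adjustment across
    loci fills ``p_holm``.
    """
    if test not in ("chi2", "fisher", "permutation"):
        raise ValueError(f"unknown test {test!r}; expected chi2|fisher|permutation")
    if test == "permutation" and n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    for c in (cohort_a, cohort_b):
        if c not in table.cohorts():
            raise KeyError(
                f"cohort {c!r} not present; available: {', '.join(table.cohorts())}"
            )
    rng = np.random.default_rng(seed)
    results: list[LocusComparison] = []
    for locus in table.locus_names:
        alleles, obs = _copy_count_matrix(table, cohort_a, cohort_b, locus)
        fa = allele_frequencies(table, cohort_a, locus)
        fb = allele_frequencies(table, cohort_b, locus)
        gained = {a: fb.freqs[a] for a in alleles if a not in fa.freqs}
        lost = {a: fa.freqs[a] for a in alleles if a not in fb.freqs}
        shared = {
            a: fb.freqs[a] / fa.freqs[a]
            for a in alleles
            if a in fa.freqs and a in fb.freqs
        }

        per_allele_p: dict[str, float] = {}
        if test == "chi2":
            stat, df = pearson_chi2(obs)
            p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
            if stat == 0.0:
                p = 1.0
        elif test == "fisher":
            totals = obs.sum(axis=0)
            pvals = []
            for i, a in enumerate(alleles):
                t22 = np.array(
                    [
                        [obs[i, 0], totals[0] - obs[i, 0]],
                        [obs[i, 1], totals[1] - obs[i, 1]],
                    ]
                )
                _, pa = stats.fisher_exact(t22)
                per_allele_p[a] = float(pa)
                pvals.append(pa)
            stat, df = pearson_chi2(obs)
            p = min(1.0, len(pvals) * min(pvals)) if pvals else 1.0
        else:  # permutation
            counts, in_a = _individual_allele_counts(
                table, (cohort_a, cohort_b), locus, alleles
            )
            stat, p = _permutation_pvalue(counts, in_a, n_perm, rng)
            df = len(alleles) - 1

        gobs = _genotype_contingency(table, cohort_a, cohort_b, locus)
        gstat, gdf = pearson_chi2(gobs)
        gp = float(stats.chi2.sf(gstat, gdf)) if gdf > 0 else 1.0
        if gstat == 0.0:
            gp = 1.0
        results.append(
            LocusComparison(
                locus=locus,
                gained=gained,
                lost=lost,
                shared_ratio=shared,
                freqs_a=dict(fa.freqs),
                freqs_b=dict(fb.freqs),
                statistic=float(stat),
                df=int(df),
                p_value=float(p),
                per_allele_p=per_allele_p,
                n_genotypes_a=count_genotypes(table, cohort_a, locus),
                n_genotypes_b=count_genotypes(table, cohort_b, locus),
                genotype_statistic=float(gstat),
                genotype_p_value=float(gp),
            )
        )
    holm = multipletests([lc.p_value for lc in results], method="holm")[1]
    results = [
        LocusComparison(**{**lc.__dict__, "p_holm": float(h)})
        for lc, h in zip(results, holm)
    ]
    return TemporalComparison(
        cohort_a=cohort_a, cohort_b=cohort_b, test=test, per_locus=tuple(results)
    )


# ---------------------------------------------------------------------------
# Trajectories


@dataclass(frozen=True)
class AlleleTrajectory:
    """Frequency series of one allele across ordered cohorts.

    ``folds`` holds the ratio of each cohort's frequency to the first
    cohort's; when the allele is absent at baseline the fold is ``None``
    and ``gained`` is set (division-by-zero guard).
    """

    locus: str
    allele: str
    cohorts: tuple[str, ...]
    freqs: tuple[float, ...]
    folds: tuple[Optional[float], ...]
    gained: bool


def frequency_trajectory(
    tables: Sequence[AlleleFrequencyTable],
) -> tuple[AlleleTrajectory, ...]:
    """Per-allele frequency series over cohorts at one locus, with folds."""
    if len(tables) < 2:
        raise ValueError("need at least two cohorts for a trajectory")
    locus = tables[0].locus
    for t in tables:
        if t.locus != locus:
            raise ValueError(
                f"inconsistent loci: {t.locus!r} vs {locus!r}"
            )
    alleles = sorted({a for t in tables for a in t.freqs})
    cohorts = tuple(t.cohort for t in tables)
    out = []
    for a in alleles:
        series = tuple(t.freqs.get(a, 0.0) for t in tables)
        base = series[0]
        if base > 0:
            folds = tuple(f / base for f in series)
            gained = False
        else:
            folds = tuple(None for _ in series)
            gained = any(f > 0 for f in series[1:])
        out.append(
            AlleleTrajectory(
                locus=locus, allele=a, cohorts=cohorts,
                freqs=series, folds=folds, gained=gained,
            )
        )
    return tuple(out)


# ---------------------------------------------------------------------------
# Report rendering


def comparison_to_tsv(cmp: TemporalComparison) -> str:
    """Per-allele comparison report: frequencies, fold, status, test columns."""
    header = (
        "locus", "allele", "freq_a", "freq_b", "fold", "status",
        "statistic", "p_raw", "p_holm",
    )
    lines = ["\t".join(header)]
    for lc in cmp.per_locus:
        alleles = sorted(set(lc.freqs_a) | set(lc.freqs_b))
        for a in alleles:
            pa = lc.freqs_a.get(a, 0.0)
            pb = lc.freqs_b.get(a, 0.0)
            if a in lc.shared_ratio:
                status, fold = "shared", f"{lc.shared_ratio[a]:.3f}"
            elif a in lc.gained:
                status, fold = "gained", ""
            else:
                status, fold = "lost", ""
            lines.append(
                "\t".join(
                    (
                        lc.locus, a, f"{pa:.3f}", f"{pb:.3f}", fold, status,
                        f"{lc.statistic:.3f}", f"{lc.p_value:.4g}",
                        f"{lc.p_holm:.4g}",
                    )
                )
            )
    return "\n".join(lines) + "\n"


def classification_to_tsv(classifications: Sequence[AlleleClassification]) -> str:
    """Classification report; rare alleles flagged ``*``, unique ``**``."""
    header = ("cohort", "locus", "allele", "freq", "class", "flag")
    lines = ["\t".join(header)]
    for c in classifications:
        all_freqs = {**c.common, **c.intermediate, **c.rare}
        for a in sorted(all_freqs):
            p = all_freqs[a]
            if a in c.common:
                klass = "common"
            elif a in c.rare:
                klass = "rare"
            else:
                klass = "intermediate"
            flag = "**" if a in c.unique else ("*" if klass == "rare" else "")
            lines.append(
                "\t".join((c.cohort, c.locus, a, f"{p:.3f}", klass, flag))
            )
    return "\n".join(lines) + "\n"
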