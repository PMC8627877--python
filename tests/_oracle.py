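"""Independent brute-force recomputation of every diversity index.

Deliberately naive: enumerates allele copies and genotype pairs as
explicit Python lists and never calls into strmonitor's diversity code,
so it can serve as the oracle in equivalence tests.
"""

from collections import Counter
from itertools import combinations
from math import comb


def brute_force_indices(genotype_pairs):
    """All indices for one locus from a list of (allele, allele) pairs.

    *genotype_pairs* holds only typed genotypes, as raw tuples in any
    order within the pair.
    """
    copies = []
    for a, b in genotype_pairs:
        copies.append(a)
        copies.append(b)
    counts = Counter(copies)
    n_typed = len(genotype_pairs)
    freqs = {a: c / (2 * n_typed) for a, c in counts.items()}
    sum_p2 = sum(p * p for p in freqs.values())
    na = len(counts)
    ae = 1.0 / sum_p2
    ho = sum(1 for a, b in genotype_pairs if a != b) / n_typed
    he = 1.0 - sum_p2
    fis = 0.0 if he == 0.0 else (he - ho) / he
    n_genotypes = len({tuple(sorted(p)) for p in genotype_pairs})
    return {
        "counts": dict(counts),
        "freqs": freqs,
        "n_typed": n_typed,
        "na": na,
        "ae": ae,
        "ho": ho,
        "he": he,
        "fis": fis,
        "n_genotypes": n_genotypes,
    }


def pearson_statistic(counts_a, counts_b):
    """Pearson chi-square over the allele union of two copy-count dicts."""
    alleles = sorted(set(counts_a) | set(counts_b))
    tot_a = sum(counts_a.values())
    tot_b = sum(counts_b.values())
    grand = tot_a + tot_b
    stat = 0.0
    for al in alleles:
        row = counts_a.get(al, 0) + counts_b.get(al, 0)
        for obs, col in ((counts_a.get(al, 0), tot_a), (counts_b.get(al, 0), tot_b)):
            e = row * col / grand
            if e > 0:
                stat += (obs - e) ** 2 / e
    return stat


def exact_permutation_pvalue(individual_pairs, n_a):
    """Exact label-shuffle null: enumerate all n-choose-n_a assignments.

    Returns the fraction of assignments whose Pearson statistic is >=
    the observed one (the first *n_a* individuals being group a).
    """
    n = len(individual_pairs)

    def stat_for(indices_a):
        ca, cb = Counter(), Counter()
        for i, pair in enumerate(individual_pairs):
            tgt = ca if i in indices_a else cb
            for al in pair:
                tgt[al] += 1
        return pearson_statistic(ca, cb)

    obs = stat_for(set(range(n_a)))
    exceed = 0
    total = comb(n, n_a)
    for combo in combinations(range(n), n_a):
        if stat_for(set(combo)) >= obs - 1e-12:
            exceed += 1
    return obs, exceed / total
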