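"""Translocation validation from recombinant-population read summaries.

A translocation predicted between two genomes has two insertion sites: one
on the haplotype of genome 1 (locus A) and one on the haplotype of genome 2
(locus B).  In an F2 population the two loci recombine independently of the
translocated DNA itself, so the copy number of the translocated sequence in
a recombinant equals (# genome-1 haplotypes at locus A) + (# genome-2
haplotypes at locus B) and ranges over 0..4.  Three tests exploit this:

* **absence** — samples expected to carry zero copies must show essentially
  no reads over the region (coverage ratio below a cut-off, default 0.2x);
  applicable only when at least two zero-copy samples exist;
* **copy-number fit** — ordinary least squares of observed copy number
  (2 x region coverage / genome coverage) on expected copy number across
  samples with different genotypes at the two loci; validated when the
  BH-adjusted one-sided p value is below 1e-6 and the slope exceeds 0.75;
* **genotype clustering** — samples sharing a two-locus genotype should
  have similar marker allele counts.  The closeness score sums, over
  genotype groups, the mean within-group distance divided by the mean
  distance to other groups (lower = tighter clustering); its null
  distribution comes from re-simulating the counts with Poisson rates taken
  from the per-group means while randomly permuting the group labels, and a
  translocation is validated when the BH-adjusted lower-tail p value is
  below 0.05.

A translocation is *confirmed* when at least one test validates it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist, pdist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "F2Sample",
    "Translocation",
    "TestResult",
    "expected_copy_number",
    "filter_translocations",
    "test_absence",
    "test_copyfit",
    "closeness_score",
    "normalize_marker_counts",
    "test_cluster",
    "validate_translocations",
    "simulate_f2_population",
]

COV_CUTOFF = 0.2          # x genome coverage: absence/presence boundary
FIT_ALPHA = 1e-6          # adjusted-p threshold for the copy-number fit
FIT_MIN_SLOPE = 0.75
CLUSTER_ALPHA = 0.05
MIN_TRANSLOC_SIZE = 1000  # bp
MAX_N_FRACTION = 0.25
N_SIM = 10_000

GENOTYPES = ("AA", "AB", "BB")


@dataclass
class F2Sample:
    """Read-data summary of one recombinant sample at one translocation.

    ``genotype_a`` / ``genotype_b`` are the genotypes at the two insertion
    loci, coded AA / AB / BB with A the genome-1 haplotype.  ``marker_counts``
    is an (n_markers, 2) array of (reference, alternate) allele counts.
    ``n_fraction`` is the fraction of region reads carrying >= 10% Ns.
    """

    sample_id: str
    genotype_a: str
    genotype_b: str
    region_coverage: float
    genome_coverage: float
    marker_counts: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    n_fraction: float = 0.0

    @property
    def coverage_ratio(self) -> float:
        return self.region_coverage / self.genome_coverage

    @property
    def observed_copy(self) -> float:
        return 2.0 * self.coverage_ratio

    @property
    def expected_copy(self) -> int:
        return expected_copy_number(self.genotype_a, self.genotype_b)


@dataclass
class Translocation:
    """A predicted translocation with its spans in both genomes."""

    id: str
    ref_chr: str
    ref_start: int
    ref_end: int
    qry_chr: str = ""
    qry_start: int = 0
    qry_end: int = 0

    @property
    def size(self) -> int:
        return self.ref_end - self.ref_start + 1


@dataclass
class TestResult:
    translocation: str
    absence: str = "not_applicable"
    copyfit: str = "not_applicable"
    cluster: str = "not_applicable"
    slope: float = float("nan")
    copyfit_p: float = float("nan")
    copyfit_p_adj: float = float("nan")
    closeness: float = float("nan")
    cluster_p: float = float("nan")
    cluster_p_adj: float = float("nan")

    @property
    def confirmed(self) -> bool:
        return "validated" in (self.absence, self.copyfit, self.cluster)


def expected_copy_number(genotype_a: str, genotype_b: str) -> int:
    """Copies of translocated DNA implied by the two-locus genotype: the
    DNA sits at locus A on the A haplotype and at locus B on the B
    haplotype, so copies = #A alleles at A + #B alleles at B."""
    for g in (genotype_a, genotype_b):
        if g not in GENOTYPES:
            raise ValueError(f"invalid genotype code {g!r}")
    return genotype_a.count("A") + genotype_b.count("B")


def filter_translocations(
    translocations: list[Translocation],
    samples: dict[str, list[F2Sample]],
    centromeres: list[tuple[str, int, int]] = (),
    min_size: int = MIN_TRANSLOC_SIZE,
    max_n_fraction: float = MAX_N_FRACTION,
) -> list[Translocation]:
    """Keep translocations that are testable: larger than ``min_size``,
    outside centromeres, and whose region is not dominated by N-containing
    reads (mean per-sample fraction above ``max_n_fraction`` fails)."""
    out = []
    for tr in translocations:
        if tr.size <= min_size:
            continue
        if any(
            c == tr.ref_chr and tr.ref_start <= ce and cs <= tr.ref_end
            for c, cs, ce in centromeres
        ):
            continue
        ss = samples.get(tr.id, [])
        if ss and float(np.mean([s.n_fraction for s in ss])) > max_n_fraction:
            continue
        out.append(tr)
    return out


def test_absence(
    translocation: Translocation,
    samples: list[F2Sample],
    cov_cutoff: float = COV_CUTOFF,
) -> str:
    """Validated when every sample expected to have lost the region indeed
    shows a coverage ratio below ``cov_cutoff``; needs >= 2 such samples."""
    zero = [s for s in samples if s.expected_copy == 0]
    if len(zero) < 2:
        return "not_applicable"
    return "validated" if all(s.coverage_ratio < cov_cutoff for s in zero) else "failed"


def test_copyfit(
    translocations: list[Translocation],
    samples: dict[str, list[F2Sample]],
    alpha: float = FIT_ALPHA,
    min_slope: float = FIT_MIN_SLOPE,
) -> dict[str, tuple[float, float, float, str]]:
    """Expected-vs-observed copy-number regression for each translocation.

    Samples with identical genotypes at the two loci are excluded (they pile
    up at two copies and bias the fit); at least three distinct expected
    values are required.  Returns id -> (slope, one-sided p, adjusted p,
    status); p values are BH-adjusted across all tested translocations.
    """
    tested: list[str] = []
    pvals: list[float] = []
    slopes: dict[str, float] = {}
    results: dict[str, tuple[float, float, float, str]] = {}
    for tr in translocations:
        sel = [s for s in samples.get(tr.id, []) if s.genotype_a != s.genotype_b]
        exp = np.array([s.expected_copy for s in sel], dtype=float)
        obs = np.array([s.observed_copy for s in sel], dtype=float)
        if len(sel) < 3 or len(set(exp)) < 3 or np.var(exp) == 0:
            results[tr.id] = (float("nan"), float("nan"), float("nan"), "not_applicable")
            continue
        fit = stats.linregress(exp, obs)
        p_one = fit.pvalue / 2.0 if fit.slope > 0 else 1.0 - fit.pvalue / 2.0
        slopes[tr.id] = fit.slope
        tested.append(tr.id)
        pvals.append(p_one)
    if tested:
        _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
        for tid, p, pa in zip(tested, pvals, p_adj):
            status = "validated" if (pa < alpha and slopes[tid] > min_slope) else "failed"
            results[tid] = (slopes[tid], p, pa, status)
    return results


# ---------------------------------------------------------------------------
# Genotype clustering (test 3)
# ---------------------------------------------------------------------------

def normalize_marker_counts(
    counts: np.ndarray, outlier_factor: float = 3.0
) -> np.ndarray:
    """Normalise an (n_samples, n_markers, 2) count array: drop outlier
    markers (mean total count above ``outlier_factor`` x the median), divide
    each sample by its total marker depth, then centre each marker."""
    counts = np.asarray(counts, dtype=float)
    marker_means = counts.sum(axis=2).mean(axis=0)
    med = np.median(marker_means)
    keep = marker_means <= outlier_factor * med if med > 0 else np.ones(len(marker_means), bool)
    counts = counts[:, keep, :]
    depth = counts.sum(axis=(1, 2), keepdims=True)
    depth[depth == 0] = 1.0
    counts = counts / depth
    return counts - counts.mean(axis=0, keepdims=True)


def closeness_score(groups: dict[str, np.ndarray]) -> float:
    """Sum over genotype groups of mean within-group distance over mean
    distance to the other groups, on flattened allele-count vectors.
    Lower values mean genotype-consistent clustering; zero between-group
    distance is degenerate and raises."""
    keys = sorted(groups)
    if len(keys) < 2:
        raise ValueError("need at least two genotype groups")
    flat = {k: np.asarray(groups[k], dtype=float).reshape(len(groups[k]), -1) for k in keys}
    score = 0.0
    for k in keys:
        g = flat[k]
        within = float(np.mean(pdist(g))) if len(g) > 1 else 0.0
        others = np.concatenate([flat[j] for j in keys if j != k])
        between = float(np.mean(cdist(g, others)))
        if between == 0:
            raise ValueError(f"zero between-group distance for group {k}")
        score += within / between
    return score


def _group_samples(samples: list[F2Sample], min_group: int = 3) -> dict[str, list[F2Sample]]:
    groups: dict[str, list[F2Sample]] = {}
    for s in samples:
        groups.setdefault(s.genotype_a + "/" + s.genotype_b, []).append(s)
    return {k: v for k, v in groups.items() if len(v) >= min_group}


def test_cluster(
    translocation: Translocation,
    samples: list[F2Sample],
    n_sim: int = N_SIM,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float, str]:
    """Observed closeness score and its lower-tail Monte-Carlo p value.

    Eligibility: >= 2 genotype classes of >= 3 samples, >= 3 markers, and
    alternate-allele counts that actually vary (variance >= 1).  The null
    background re-draws every sample's counts from a Poisson whose rate is
    the observed mean of a randomly re-assigned genotype group, scoring
    against the original grouping; p uses a +1 pseudo-count.
    Returns (score, p, status) with status 'tested' or 'not_applicable'.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups = _group_samples(samples)
    if len(groups) < 2:
        return float("nan"), float("nan"), "not_applicable"
    used = [s for g in sorted(groups) for s in groups[g]]
    m = used[0].marker_counts.shape[0]
    if m < 3 or any(s.marker_counts.shape[0] != m for s in used):
        return float("nan"), float("nan"), "not_applicable"
    raw = np.stack([s.marker_counts for s in used]).astype(float)  # (n, m, 2)
    # alternate counts that do not change across samples carry no signal
    if float(np.mean(np.var(raw[:, :, 1], axis=0))) < 1.0:
        return float("nan"), float("nan"), "not_applicable"
    labels = np.array(
        [k for k in sorted(groups) for _ in groups[k]]
    )
    norm = normalize_marker_counts(raw)
    obs = closeness_score({k: norm[labels == k] for k in sorted(groups)})

    group_rates = {k: raw[labels == k].mean(axis=0) for k in sorted(groups)}
    n = len(used)
    hits = 0
    for _ in range(n_sim):
        perm = rng.permutation(n)
        rates = np.stack([group_rates[labels[perm[i]]] for i in range(n)])
        sim = rng.poisson(rates)
        sim_norm = normalize_marker_counts(sim)
        try:
            s = closeness_score({k: sim_norm[labels == k] for k in sorted(groups)})
        except ValueError:
            continue
        if s <= obs:
            hits += 1
    p = (1 + hits) / (1 + n_sim)
    return obs, p, "tested"


def validate_translocations(
    translocations: list[Translocation],
    samples: dict[str, list[F2Sample]],
    centromeres: list[tuple[str, int, int]] = (),
    n_sim: int = N_SIM,
    seed: int | np.random.Generator | None = None,
    cov_cutoff: float = COV_CUTOFF,
) -> list[TestResult]:
    """Run all three tests over the testable translocations and report
    per-translocation statuses; BH adjustment is applied across
    translocations within each p-value-based test."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    testable = filter_translocations(translocations, samples, centromeres)
    results = {tr.id: TestResult(tr.id) for tr in testable}

    for tr in testable:
        results[tr.id].absence = test_absence(tr, samples.get(tr.id, []), cov_cutoff)

    for tid, (slope, p, p_adj, status) in test_copyfit(testable, samples).items():
        r = results[tid]
        r.slope, r.copyfit_p, r.copyfit_p_adj, r.copyfit = slope, p, p_adj, status

    tested: list[str] = []
    pvals: list[float] = []
    for tr in testable:
        score, p, status = test_cluster(tr, samples.get(tr.id, []), n_sim, rng)
        r = results[tr.id]
        r.closeness = score
        if status == "tested":
            r.cluster_p = p
            tested.append(tr.id)
            pvals.append(p)
    if tested:
        _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
        for tid, pa in zip(tested, p_adj):
            results[tid].cluster_p_adj = pa
            results[tid].cluster = "validated" if pa < CLUSTER_ALPHA else "failed"
    return [results[tr.id] for tr in testable]


def results_frame(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "translocation": [r.translocation for r in results],
            "absence": [r.absence for r in results],
            "copyfit": [r.copyfit for r in results],
            "cluster": [r.cluster for r in results],
            "slope": [r.slope for r in results],
            "copyfit_p_adj": [r.copyfit_p_adj for r in results],
            "closeness": [r.closeness for r in results],
            "cluster_p_adj": [r.cluster_p_adj for r in results],
            "confirmed": [r.confirmed for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Synthetic F2 cohort
# ---------------------------------------------------------------------------

def simulate_f2_population(
    n_samples: int = 50,
    depth: float = 5.0,
    translocation: Translocation | None = None,
    seed: int | np.random.Generator | None = None,
    n_markers: int = 10,
    read_len: int = 150,
    null: bool = False,
) -> list[F2Sample]:
    """Simulate read-data summaries for an F2 cohort at one translocation.

    Genotypes at the two loci segregate 1:2:1 independently.  Region read
    counts are Poisson with mean proportional to the copy number (copy 2 =
    genome average), marker allele counts are Poisson with the reference
    rate tracking the A-haplotype dose at locus A and the alternate rate
    the B-haplotype dose at locus B.  With ``null=True`` the region behaves
    like ordinary two-copy sequence and marker counts ignore genotype,
    emulating a mis-predicted translocation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    region_len = translocation.size if translocation is not None else 5000
    out: list[F2Sample] = []
    for i in range(n_samples):
        ga = GENOTYPES[rng.choice(3, p=[0.25, 0.5, 0.25])]
        gb = GENOTYPES[rng.choice(3, p=[0.25, 0.5, 0.25])]
        copies = 2 if null else expected_copy_number(ga, gb)
        n_frag = region_len / read_len
        reads = rng.poisson(depth * (copies / 2.0) * n_frag)
        region_cov = reads * read_len / region_len
        if null:
            ref = rng.poisson(depth / 2.0, size=n_markers)
            alt = rng.poisson(depth / 2.0, size=n_markers)
        else:
            n_a = ga.count("A")
            n_b = gb.count("B")
            ref = rng.poisson(depth * n_a / 2.0, size=n_markers)
            alt = rng.poisson(depth * n_b / 2.0, size=n_markers)
        out.append(
            F2Sample(
                sample_id=f"s{i + 1}",
                genotype_a=ga,
                genotype_b=gb,
                region_coverage=float(region_cov),
                genome_coverage=float(depth),
                marker_counts=np.stack([ref, alt], axis=1),
            )
        )
    return out
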