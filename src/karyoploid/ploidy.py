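"""Ploidy inference from biallelic allele-frequency distributions.

At a heterozygous biallelic site, the expected alternate-allele read
frequency depends on the allelic dosage: 1/2 for a diploid, 1/3 or 2/3 for
a triploid, 1/4, 1/2 or 3/4 for a tetraploid.  Pooling many sites, the
frequency histogram is a mixture of components centred on those values,
and the ploidy can be read off by comparing fixed-mean Gaussian mixtures
(one per candidate ploidy) against a free-mean mixture of the same size:

* ``delta log-likelihood`` — loglik(free) - loglik(fixed); the smaller the
  delta, the less is lost by pinning the means to the ploidy's values, so
  the candidate with the lowest delta is preferred;
* ``histogram fit`` — ordinary least squares of the empirical histogram on
  the fitted fixed model's expected bin heights; a good candidate shows a
  positive slope near 1 with small standard error, small sum of squared
  residuals (SSR) and large R^2;
* ``median allele ratio`` — the per-site ratio of the more frequent over
  the less frequent allele's read count; its median separates ploidy
  classes, and a query sample whose median falls within the range spanned
  by reference samples of known ploidy is called to that ploidy.

Mixtures are fitted by EM on mixture weights and per-component standard
deviations; the free model also updates means.  An optional uniform noise
component absorbs sites that fit no dosage class (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PLOIDY_MEANS = {
    2: (0.5,),
    3: (1 / 3, 2 / 3),
    4: (0.25, 0.5, 0.75),
}

PLOIDY_NAMES = {2: "diploid", 3: "triploid", 4: "tetraploid"}

#: site filters applied by default: minimum total coverage and minimum
#: reads supporting the minor allele (both alleles must be seen)
DEFAULT_MIN_COVERAGE = 10
DEFAULT_MIN_MINOR_READS = 2

SD_FLOOR = 1e-3


class PloidyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# site loading and allele ratios
# ---------------------------------------------------------------------------


def load_site_counts(
    source,
    sample: str | None = None,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    min_minor_reads: int = DEFAULT_MIN_MINOR_READS,
) -> tuple[pd.DataFrame, dict]:
    """Load per-site biallelic read counts with filtering.

    ``source`` is a DataFrame with ``ref_reads``/``alt_reads`` columns, a
    path to a TSV with those columns, or a path to a VCF with per-sample
    allele depths (AD) — then ``sample`` selects the sample.  Returns the
    kept sites and a log of how many sites each filter discarded (nothing
    is dropped silently).
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        path = str(source)
        if path.endswith((".vcf", ".vcf.gz", ".bcf")):
            from karyoploid.io import read_allele_depths

            df = read_allele_depths(path, sample)
        else:
            df = pd.read_csv(path, sep="\t")
    for col in ("ref_reads", "alt_reads"):
        if col not in df.columns:
            raise PloidyError(f"input lacks required column {col!r}")
    n0 = len(df)
    cov = df["ref_reads"] + df["alt_reads"]
    keep_cov = cov >= min_coverage
    minor = df[["ref_reads", "alt_reads"]].min(axis=1)
    keep_minor = minor >= min_minor_reads
    kept = df[keep_cov & keep_minor].reset_index(drop=True)
    log = {
        "input_sites": n0,
        "dropped_low_coverage": int((~keep_cov).sum()),
        "dropped_low_minor": int((keep_cov & ~keep_minor).sum()),
        "kept": len(kept),
    }
    return kept, log


def alt_frequencies(sites: pd.DataFrame) -> np.ndarray:
    """Alternate-allele frequencies in the open interval (0, 1); sites
    where only one allele was observed are not biallelic in-sample and are
    excluded."""
    cov = (sites["ref_reads"] + sites["alt_reads"]).to_numpy(float)
    alt = sites["alt_reads"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = alt / cov
    return f[(f > 0) & (f < 1)]


def allele_ratio_stats(sites: pd.DataFrame) -> tuple[float, np.ndarray]:
    """Per-site allele ratios (reads of the more frequent allele divided
    by reads of the less frequent allele) and their median.

    Sites where either allele is unobserved are excluded; if none remain
    the input is effectively monoallelic and an error is raised.
    """
    ref = sites["ref_reads"].to_numpy(float)
    alt = sites["alt_reads"].to_numpy(float)
    both = (ref > 0) & (alt > 0)
    if not both.any():
        raise PloidyError("all sites monoallelic after filtering")
    hi = np.maximum(ref[both], alt[both])
    lo = np.minimum(ref[both], alt[both])
    ratios = hi / lo
    return float(np.median(ratios)), ratios


# ---------------------------------------------------------------------------
# mixture fitting
# ---------------------------------------------------------------------------


@dataclass
class MixtureFit:
    """A fitted Gaussian mixture over allele frequencies."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    noise_weight: float
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: list = field(default_factory=list, repr=False)

    def bin_expectation(self, edges: np.ndarray, n: int) -> np.ndarray:
        """Expected histogram counts per bin for n sites."""
        exp = np.zeros(len(edges) - 1)
        for w, m, s in zip(self.weights, self.means, self.sds):
            cdf = stats.norm.cdf(edges, loc=m, scale=s)
            exp += w * np.diff(cdf)
        if self.noise_weight > 0:
            exp += self.noise_weight * np.diff(edges)
        return n * exp


def fit_mixture(
    freqs: np.ndarray,
    ploidy: int | str,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int | None = None,
    denoise: bool = False,
    shared_sd: bool = True,
    init: tuple | None = None,
) -> MixtureFit:
    """EM fit of a Gaussian mixture to allele frequencies.

    ``ploidy`` 2/3/4 fixes the component means at the dosage expectations
    and fits weights and standard deviations; ``"free:K"`` (or the integer
    K via ``("free", K)``) also updates the K means.  With ``denoise`` a
    uniform(0,1) noise component with its own weight is included.

    By default one standard deviation is shared by all components
    (homoscedastic mixture): read-sampling spread is nearly the same at
    every dosage mean, and per-component deviations let spare components
    of an over-rich model collapse onto a handful of tail sites, inflating
    its likelihood spuriously.  ``shared_sd=False`` restores per-component
    deviations.

    The log-likelihood is non-decreasing across iterations;
    non-convergence within ``max_iter`` is flagged, returning the best fit
    so far.
    """
    x = np.asarray(freqs, dtype=float)
    if len(x) < 50:
        raise PloidyError(f"need >= 50 sites to fit a mixture, got {len(x)}")
    if isinstance(ploidy, tuple):
        free, k = True, int(ploidy[1])
    elif isinstance(ploidy, str):
        if not ploidy.startswith("free"):
            raise PloidyError(f"unknown model {ploidy!r}")
        free, k = True, int(ploidy.split(":")[1]) if ":" in ploidy else 1
    else:
        if ploidy not in PLOIDY_MEANS:
            raise PloidyError(f"unsupported ploidy {ploidy}")
        free, k = False, len(PLOIDY_MEANS[ploidy])

    if init is not None:
        means, sds, weights = (np.array(v, dtype=float) for v in init)
        means, sds, weights = means.copy(), sds.copy(), weights.copy()
    elif free:
        # deterministic spread initialization over the data quantiles
        qs = np.linspace(0.25, 0.75, k) if k > 1 else np.array([0.5])
        means = np.quantile(x, qs)
        sds = np.full(k, 0.1)
        weights = np.full(k, 1.0 / k)
    else:
        means = np.array(PLOIDY_MEANS[ploidy], dtype=float)
        sds = np.full(k, 0.1)
        weights = np.full(k, 1.0 / k)
    noise_w = 0.05 if denoise else 0.0
    if denoise:
        weights *= 1 - noise_w

    prev_ll = -np.inf
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        comp = np.empty((k + (1 if denoise else 0), len(x)))
        for j in range(k):
            comp[j] = weights[j] * stats.norm.pdf(x, means[j], sds[j])
        if denoise:
            comp[k] = noise_w  # uniform(0,1) density is 1
        tot = comp.sum(axis=0)
        tot = np.maximum(tot, 1e-300)
        ll = float(np.log(tot).sum())
        trace.append(ll)
        if ll - prev_ll < tol and it > 1:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
        resp = comp / tot
        nk = resp.sum(axis=1)
        for j in range(k):
            if nk[j] <= 0:
                continue
            if free:
                means[j] = float(resp[j] @ x / nk[j])
        if shared_sd:
            num = sum(float(resp[j] @ (x - means[j]) ** 2) for j in range(k))
            sds[:] = max(np.sqrt(num / max(nk[:k].sum(), 1e-12)), SD_FLOOR)
        else:
            for j in range(k):
                if nk[j] <= 0:
                    continue
                var = float(resp[j] @ (x - means[j]) ** 2 / nk[j])
                sds[j] = max(np.sqrt(var), SD_FLOOR)
        weights = nk[:k] / len(x)
        if denoise:
            noise_w = float(nk[k] / len(x))
    return MixtureFit(
        means=means,
        sds=sds,
        weights=weights,
        noise_weight=noise_w,
        loglik=prev_ll,
        n_iter=it,
        converged=converged,
        loglik_trace=trace,
    )


# ---------------------------------------------------------------------------
# histogram comparison
# ---------------------------------------------------------------------------


def histotest_stats(
    empirical: np.ndarray, expected: np.ndarray
) -> tuple[float, float, float, float]:
    """OLS of empirical histogram heights on expected heights.

    Returns (slope, slope standard error, sum of squared residuals, R^2).
    A perfect match gives slope 1, SSR 0, R^2 1.
    """
    y = np.asarray(empirical, float)
    x = np.asarray(expected, float)
    if len(x) != len(y) or len(x) < 3:
        raise PloidyError("need >= 3 matching histogram bins")
    if not (np.any(x > 0) and np.any(y > 0)):
        raise PloidyError("empty histograms")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    ssr = float(resid @ resid)
    return float(res.slope), float(res.stderr), ssr, float(res.rvalue**2)


def histotest(
    freqs: np.ndarray,
    ploidy: int,
    bins: int = 30,
    fit: MixtureFit | None = None,
    **fit_kwargs,
) -> tuple[float, float, float, float]:
    """Histogram comparison against a fixed-ploidy mixture.

    Bins the frequencies into ``bins`` equal bins on (0, 1), integrates
    the fitted fixed model per bin, and regresses empirical on expected
    counts.  Returns (slope, slope_se, SSR, R^2).
    """
    x = np.asarray(freqs, float)
    if fit is None:
        fit = fit_mixture(x, ploidy, **fit_kwargs)
    edges = np.linspace(0.0, 1.0, bins + 1)
    empirical, _ = np.histogram(x, bins=edges)
    expected = fit.bin_expectation(edges, len(x))
    return histotest_stats(empirical, expected)


# ---------------------------------------------------------------------------
# the full report and the four-criterion call
# ---------------------------------------------------------------------------


@dataclass
class PloidyFitReport:
    """Per-ploidy model comparison for one sample."""

    sample: str
    n_sites: int
    loglik_fixed: dict
    loglik_free: dict
    delta_loglik: dict
    histo: dict  # ploidy -> (slope, slope_se, ssr, r2)
    median_allele_ratio: float
    em_iterations: dict
    converged: dict
    known_ploidy: int | None = None

    #: a fixed model within this many log-likelihood units per site of the
    #: free model fits the data adequately.  Lower-ploidy models are nested
    #: in higher ones (a diploid frequency cloud is a tetraploid mixture
    #: with all weight on the middle component), so raw likelihood alone
    #: can never favour the simpler model; the call is therefore the
    #: lowest ploidy whose delta is adequate.  Under capture-style depth
    #: overdispersion, adequate fits show deltas up to ~0.01 per site
    #: (heavy frequency tails that a richer free model always exploits a
    #: little), while models of the wrong ploidy misfit at >= 0.13 per
    #: site; 0.02 separates the regimes with >= 6x margin on either side.
    delta_adequate_per_site = 0.02

    @property
    def best_by_delta(self) -> int:
        tol = self.delta_adequate_per_site * max(self.n_sites, 1)
        adequate = [p for p, d in self.delta_loglik.items() if d <= tol]
        if adequate:
            return min(adequate)
        return min(self.delta_loglik, key=self.delta_loglik.get)

    @property
    def best_by_histo_r2(self) -> int:
        return max(self.histo, key=lambda p: self.histo[p][3])

    @classmethod
    def from_dict(cls, d: dict) -> "PloidyFitReport":
        return cls(
            sample=d["sample"],
            n_sites=d["n_sites"],
            loglik_fixed={int(k): v for k, v in d["loglik_fixed"].items()},
            loglik_free={int(k): v for k, v in d["loglik_free"].items()},
            delta_loglik={int(k): v for k, v in d["delta_loglik"].items()},
            histo={
                int(k): (v["slope"], v["slope_se"], v["ssr"], v["r2"])
                for k, v in d["histotest"].items()
            },
            median_allele_ratio=d["median_allele_ratio"],
            em_iterations={int(k): tuple(v)
                           for k, v in d["em_iterations"].items()},
            converged={int(k): tuple(v) for k, v in d["converged"].items()},
            known_ploidy=d.get("known_ploidy"),
        )

    def to_dict(self) -> dict:
        return {
            "sample": self.sample,
            "n_sites": self.n_sites,
            "loglik_fixed": {str(k): v for k, v in self.loglik_fixed.items()},
            "loglik_free": {str(k): v for k, v in self.loglik_free.items()},
            "delta_loglik": {str(k): v for k, v in self.delta_loglik.items()},
            "histotest": {
                str(k): dict(zip(("slope", "slope_se", "ssr", "r2"), v))
                for k, v in self.histo.items()
            },
            "median_allele_ratio": self.median_allele_ratio,
            "em_iterations": {str(k): v for k, v in self.em_iterations.items()},
            "converged": {str(k): v for k, v in self.converged.items()},
            "best_by_delta": self.best_by_delta,
            "known_ploidy": self.known_ploidy,
        }


def ploidy_fit_report(
    sites: pd.DataFrame,
    sample: str = "sample",
    ploidies: tuple[int, ...] = (2, 3, 4),
    bins: int = 30,
    seed: int | None = None,
    denoise: bool = False,
    known_ploidy: int | None = None,
    **fit_kwargs,
) -> PloidyFitReport:
    """Fit all candidate ploidy models plus size-matched free models and
    collect the comparison statistics for one sample."""
    freqs = alt_frequencies(sites)
    median, _ = allele_ratio_stats(sites)
    # one shared free-mean mixture, sized to the richest fixed model, is
    # the common yardstick: delta_p = loglik(free) - loglik(fixed_p).  The
    # free fit is restarted from every fixed solution (padding means when
    # the fixed model is smaller), so it truly nests each fixed model and
    # delta_p >= 0 up to EM tolerance.
    k_free = max(len(PLOIDY_MEANS[p]) for p in ploidies)
    fixed_fits = {
        p: fit_mixture(freqs, p, seed=seed, denoise=denoise, **fit_kwargs)
        for p in ploidies
    }
    free_starts = [None]
    for p, fx in fixed_fits.items():
        kp = len(fx.means)
        pad = k_free - kp
        means = np.concatenate([fx.means, np.repeat(fx.means[-1], pad)])
        sds = np.concatenate([fx.sds, np.repeat(fx.sds[-1], pad)])
        w = np.concatenate([fx.weights, np.zeros(pad)])
        if pad:
            w[kp - 1:] = w[kp - 1] / (pad + 1)
        free_starts.append((means, sds, w))
    fr = None
    for ini in free_starts:
        cand = fit_mixture(
            freqs, ("free", k_free), seed=seed, denoise=denoise,
            init=ini, **fit_kwargs,
        )
        if fr is None or cand.loglik > fr.loglik:
            fr = cand
    ll_fix, ll_free, delta, histo, iters, conv = {}, {}, {}, {}, {}, {}
    for p in ploidies:
        fx = fixed_fits[p]
        ll_fix[p] = fx.loglik
        ll_free[p] = fr.loglik
        delta[p] = fr.loglik - fx.loglik
        histo[p] = histotest(freqs, p, bins=bins, fit=fx)
        iters[p] = (fx.n_iter, fr.n_iter)
        conv[p] = (fx.converged, fr.converged)
    return PloidyFitReport(
        sample=sample,
        n_sites=len(freqs),
        loglik_fixed=ll_fix,
        loglik_free=ll_free,
        delta_loglik=delta,
        histo=histo,
        median_allele_ratio=median,
        em_iterations=iters,
        converged=conv,
        known_ploidy=known_ploidy,
    )


@dataclass
class PloidyCall:
    """Four-criterion ploidy decision for one query sample."""

    call: str  # diploid / triploid / tetraploid / ambiguous
    ploidy: int | None
    criteria: dict  # four named booleans
    reference_limits: tuple[float, float]
    delta_choice: int
    reference_ploidy: int


def call_ploidy(
    report: PloidyFitReport,
    reference_reports: list[PloidyFitReport],
    r2_min: float = 0.8,
) -> PloidyCall:
    """Apply the four decision criteria to a query sample.

    References must have ``known_ploidy`` set (all the same); their lowest
    and highest median allele ratios become the acceptance limits for the
    query's median (criterion iv).  Criterion ii is the lowest
    delta-log-likelihood; criterion iii requires a positive slope and
    R^2 >= ``r2_min`` for the chosen ploidy's histogram fit; criterion i is
    satisfied when the best histogram R^2 points at the same ploidy as the
    delta criterion.  The call is made only when the delta choice and the
    median-ratio placement agree; otherwise it is ``ambiguous``.
    """
    if not reference_reports:
        raise PloidyError("need at least one reference report of known ploidy")
    ref_p = {r.known_ploidy for r in reference_reports}
    if None in ref_p or len(ref_p) != 1:
        raise PloidyError("reference reports must share one known ploidy")
    ref_ploidy = ref_p.pop()
    medians = [r.median_allele_ratio for r in reference_reports]
    lo, hi = min(medians), max(medians)

    p_delta = report.best_by_delta
    within = lo <= report.median_allele_ratio <= hi
    slope, _se, _ssr, r2 = report.histo[p_delta]
    criteria = {
        "histogram_shape": report.best_by_histo_r2 == p_delta,
        "delta_loglik": True,  # the choice itself; recorded for the record
        "histotest_quality": slope > 0 and r2 >= r2_min,
        "median_ratio_within_limits": within,
    }
    # agreement: the median criterion and the delta choice must point the
    # same way (query is / is not the references' ploidy)
    agree = within == (p_delta == ref_ploidy)
    if agree:
        call = PLOIDY_NAMES[p_delta]
        ploidy = p_delta
    else:
        call, ploidy = "ambiguous", None
    return PloidyCall(
        call=call,
        ploidy=ploidy,
        criteria=criteria,
        reference_limits=(lo, hi),
        delta_choice=p_delta,
        reference_ploidy=ref_ploidy,
    )


def plot_frequency_histogram(
    freqs: np.ndarray,
    fits: dict[int, MixtureFit] | None,
    path,
    bins: int = 30,
    title: str = "",
) -> None:
    """Write the allele-frequency histogram (with fitted model curves
    overlaid when given) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.asarray(freqs, float)
    ax.hist(x, bins=np.linspace(0, 1, bins + 1), color="#7799bb",
            edgecolor="white", label=f"{len(x)} sites")
    if fits:
        grid = np.linspace(0.001, 0.999, 400)
        binw = 1.0 / bins
        for p, fit in sorted(fits.items()):
            dens = np.zeros_like(grid)
            for w, m, s in zip(fit.weights, fit.means, fit.sds):
                dens += w * stats.norm.pdf(grid, m, s)
            dens += fit.noise_weight
            ax.plot(grid, dens * len(x) * binw, label=PLOIDY_NAMES.get(p, str(p)))
    ax.set_xlabel("alternate-allele frequency")
    ax.set_ylabel("sites")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
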