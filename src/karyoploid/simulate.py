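"""Seeded generators for synthetic inputs with known ground truth.

Each generator emulates the statistical structure one analysis stage
assumes, so the whole pipeline is testable without any sequencing download:

* read counts over biallelic sites at a chosen ploidy, with
  negative-binomial depth (capture data are overdispersed relative to
  Poisson) and a symmetric base-calling error;
* four-taxon site-pattern matrices with a tunable introgression fraction
  and a closed-form expected D recorded in the truth record;
* multi-cluster genotype tables with exact requested shared / unique /
  singleton SNP counts;
* random rearrangement scenarios applied to a karyotype, for search
  recovery tests.

The quartet generator is a site-pattern multinomial, not a coalescent
simulation: sufficient to calibrate D and its jackknife, no more.  All
outputs are fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from karyoploid.karyotype import (
    EET,
    HEAD,
    PERI_INV,
    RECIP_TRANSLOC,
    TAIL,
    UNEQ_TRANSLOC,
    Karyotype,
    KaryotypeError,
    RearrangementEvent,
    Scenario,
    apply_event,
)

#: per-ploidy default dosage probabilities over alternate-allele dosage
#: 1..ploidy-1 (heterozygous classes only; balanced classes are rarer
#: because intermediate dosages arise from fewer mutational routes)
DEFAULT_DOSAGE_PROBS = {
    2: {1: 1.0},
    3: {1: 0.5, 2: 0.5},
    4: {1: 0.4, 2: 0.2, 3: 0.4},
}


@dataclass(frozen=True)
class SimConfig:
    """Shared configuration of the synthetic generators.

    Only the fields a given generator uses matter to it.  ``seed`` fully
    determines every output.  Depth is negative-binomial with mean
    ``mean_depth`` and dispersion ``overdispersion`` (smaller = more
    overdispersed); ``base_error`` shrinks the expected alternate-allele
    frequency symmetrically toward the opposite allele.  Quartet parameters:
    ``b`` the baseline probability weight of each discordant pattern,
    ``g`` the fraction of informative sites, ``gamma`` the introgression
    fraction shifting weight from BABA to ABBA.
    """

    seed: int = 0
    n_sites: int = 5_000
    mean_depth: float = 40.0
    overdispersion: float = 5.0
    base_error: float = 0.01
    ploidy: int = 4
    dosage_probs: dict[int, float] | None = None
    # quartet site-pattern parameters
    b: float = 0.1
    g: float = 0.5
    gamma: float = 0.0
    # random-scenario parameters
    k_events: int = 3
    allowed_operators: tuple[str, ...] = (
        EET, RECIP_TRANSLOC, UNEQ_TRANSLOC, PERI_INV,
    )

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 3, 4):
            raise ValueError("ploidy must be 2, 3 or 4")
        if self.mean_depth <= 0 or self.overdispersion <= 0:
            raise ValueError("degenerate depth parameters")
        if not (0 <= self.base_error < 0.5):
            raise ValueError("base_error must be in [0, 0.5)")
        for name, v in (("b", self.b), ("g", self.g), ("gamma", self.gamma)):
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.b == 0 and self.gamma == 0 and self.g > 0:
            raise ValueError("b and gamma cannot both be zero")
        if self.k_events < 0:
            raise ValueError("k_events must be >= 0")
        probs = self.dosage_probs
        if probs is not None:
            if set(probs) - set(range(1, self.ploidy)):
                raise ValueError("dosages must lie in 1..ploidy-1")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError("dosage probabilities must sum to 1")

    def resolved_dosage_probs(self) -> dict[int, float]:
        return dict(self.dosage_probs or DEFAULT_DOSAGE_PROBS[self.ploidy])


def _nb_depths(rng, n, mean, dispersion) -> np.ndarray:
    # negative binomial parameterized by mean and dispersion r:
    # p = r / (r + mean); zero draws are lifted to 1 (a covered site)
    p = dispersion / (dispersion + mean)
    d = rng.negative_binomial(dispersion, p, size=n)
    return np.maximum(d, 1)


def simulate_allele_counts(cfg: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Biallelic per-site read counts for one sample of known ploidy.

    Per site: alternate dosage d drawn from the dosage probabilities, depth
    from the negative binomial, alternate reads from Binomial(depth,
    p_eff) with p_eff = (d/ploidy)(1-e) + (1-d/ploidy)e.  Returns a
    DataFrame (site_id, ref_reads, alt_reads) and a truth record with the
    generating ploidy and per-site dosages.
    """
    rng = np.random.default_rng(cfg.seed)
    probs = cfg.resolved_dosage_probs()
    dosages = rng.choice(
        list(probs), size=cfg.n_sites, p=list(probs.values())
    ).astype(int)
    depth = _nb_depths(rng, cfg.n_sites, cfg.mean_depth, cfg.overdispersion)
    frac = dosages / cfg.ploidy
    p_eff = frac * (1 - cfg.base_error) + (1 - frac) * cfg.base_error
    alt = rng.binomial(depth, p_eff)
    df = pd.DataFrame(
        {
            "site_id": [f"s{i:06d}" for i in range(cfg.n_sites)],
            "ref_reads": depth - alt,
            "alt_reads": alt,
        }
    )
    truth = {
        "generator": "simulate_allele_counts",
        "seed": cfg.seed,
        "ploidy": cfg.ploidy,
        "dosage_probs": {str(k): v for k, v in probs.items()},
        "mean_depth": cfg.mean_depth,
        "base_error": cfg.base_error,
        "dosages": dosages.tolist(),
    }
    return df, truth


def expected_quartet_d(cfg: SimConfig) -> float:
    """Closed-form E[D] of the quartet generator: gamma / (2b + gamma)."""
    if cfg.b == 0 and cfg.gamma == 0:
        return 0.0
    return cfg.gamma / (2 * cfg.b + cfg.gamma)


def simulate_quartet_snps(cfg: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Four-taxon biallelic site patterns (((P1,P2),P3),O).

    With probability ``g`` a site is phylogenetically informative for the
    ABBA/BABA contrast and the two patterns are drawn with weights
    (b + gamma, b); gene flow between P2 and P3 thus inflates ABBA.
    Remaining sites carry concordant (BBAA) or singleton variation that no
    D computation counts.  The outgroup is fixed ancestral (0).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sites
    m = np.zeros((n, 4), dtype=np.int8)
    informative = rng.random(n) < cfg.g
    denom = 2 * cfg.b + cfg.gamma
    p_abba = (cfg.b + cfg.gamma) / denom if denom > 0 else 0.5
    abba = informative & (rng.random(n) < p_abba)
    baba = informative & ~abba
    m[abba, 1] = 1  # P2
    m[abba, 2] = 1  # P3
    m[baba, 0] = 1  # P1
    m[baba, 2] = 1  # P3
    other = ~informative
    kind = rng.integers(0, 4, size=n)
    bbaa = other & (kind == 0)
    m[bbaa, 0] = 1
    m[bbaa, 1] = 1
    for ki, col in ((1, 0), (2, 1), (3, 2)):  # singletons on P1/P2/P3
        sel = other & (kind == ki)
        m[sel, col] = 1
    df = pd.DataFrame(m, columns=["P1", "P2", "P3", "O"])
    truth = {
        "generator": "simulate_quartet_snps",
        "seed": cfg.seed,
        "b": cfg.b,
        "g": cfg.g,
        "gamma": cfg.gamma,
        "expected_D": expected_quartet_d(cfg),
        "n_abba_true": int(abba.sum()),
        "n_baba_true": int(baba.sum()),
    }
    return df, truth


# ---------------------------------------------------------------------------
# random rearrangement scenarios
# ---------------------------------------------------------------------------


def _random_breakpoint(rng, c, interior_ok=True) -> dict | None:
    """A random breakpoint on chromosome ``c``: a junction gap or the
    midpoint of a random segment (midpoints keep cut fractions on the
    dyadic grid the search's implied-cut policy reconstructs)."""
    choices = []
    for g in range(1, len(c.segments)):
        if g != c.cen:
            s = c.segments[g]
            coord = s.start if s.orient > 0 else s.end
            choices.append({"chrom": c.name, "block": s.block, "coord": coord,
                            "copy": s.copy})
    if interior_ok:
        for s in c.segments:
            mid = (s.start + s.end) / 2
            choices.append({"chrom": c.name, "block": s.block, "coord": mid,
                            "copy": s.copy})
    if not choices:
        return None
    return choices[rng.integers(0, len(choices))]


def random_scenario(
    cfg: SimConfig, start: Karyotype
) -> tuple[Scenario, Karyotype]:
    """Apply ``cfg.k_events`` valid random events to ``start``.

    Events that fail a precondition or leave the karyotype canonically
    unchanged are rejection-sampled (at most 1 000 rejections per event).
    Returns the scenario and the resulting karyotype for search-recovery
    tests.
    """
    rng = np.random.default_rng(cfg.seed)
    k = start
    events: list[RearrangementEvent] = []
    for step in range(cfg.k_events):
        for attempt_i in range(1_000):
            kind = cfg.allowed_operators[
                rng.integers(0, len(cfg.allowed_operators))
            ]
            chroms = k.chromosomes
            try:
                if kind == EET:
                    if len(chroms) < 2:
                        continue
                    i, j = rng.choice(len(chroms), size=2, replace=False)
                    a, b = chroms[i], chroms[j]
                    ev = RearrangementEvent(EET, {
                        "chr_a": a.name,
                        "end_a": (HEAD, TAIL)[rng.integers(0, 2)],
                        "chr_b": b.name,
                        "end_b": (HEAD, TAIL)[rng.integers(0, 2)],
                        "keep_centromere_of": (a.name, b.name)[rng.integers(0, 2)],
                        "name": f"r{step}",
                    })
                elif kind == RECIP_TRANSLOC:
                    if len(chroms) < 2:
                        continue
                    i, j = rng.choice(len(chroms), size=2, replace=False)
                    bp1 = _random_breakpoint(rng, chroms[i])
                    bp2 = _random_breakpoint(rng, chroms[j])
                    if bp1 is None or bp2 is None:
                        continue
                    ev = RearrangementEvent(
                        RECIP_TRANSLOC, {"bp1": bp1, "bp2": bp2}
                    )
                elif kind == UNEQ_TRANSLOC:
                    if len(chroms) < 2:
                        continue
                    i, j = rng.choice(len(chroms), size=2, replace=False)
                    bp = _random_breakpoint(rng, chroms[i])
                    if bp is None:
                        continue
                    ev = RearrangementEvent(UNEQ_TRANSLOC, {
                        "bp": bp,
                        "target_chr": chroms[j].name,
                        "target_end": (HEAD, TAIL)[rng.integers(0, 2)],
                    })
                else:  # PERI_INV
                    i = rng.integers(0, len(chroms))
                    c = chroms[i]
                    bpl = _random_breakpoint(rng, c)
                    bpr = _random_breakpoint(rng, c)
                    if bpl is None or bpr is None:
                        continue
                    ev = RearrangementEvent(PERI_INV, {
                        "chrom": c.name, "bp_left": bpl, "bp_right": bpr,
                    })
                k2 = apply_event(k, ev)
            except KaryotypeError:
                continue
            if k2.canonical_key() == k.canonical_key():
                continue  # identity event, resample
            k = k2
            events.append(ev)
            break
        else:
            raise KaryotypeError(
                f"could not place a valid event at step {step} "
                "after 1000 rejections"
            )
    return Scenario(tuple(events), start="custom"), k


# ---------------------------------------------------------------------------
# cluster genotype tables
# ---------------------------------------------------------------------------


def make_cluster_genotypes(
    shared: int,
    unique: dict[str, int],
    singletons: int,
    n_per_cluster: int = 6,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Presence/absence genotype table with exact partition structure.

    Builds ``n_per_cluster`` samples per cluster and SNP columns such that
    exactly ``shared`` SNPs carry the alternate allele in at least one
    member of every cluster, exactly ``unique[c]`` SNPs are carried only
    within cluster ``c`` by at least two samples (so they survive singleton
    filtering), and exactly ``singletons`` SNPs are carried by one sample
    overall.  Returns the 0/1 table (samples x SNPs) and the expected
    partition as a truth record.
    """
    clusters = sorted(unique)
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    if shared < 0 or singletons < 0 or any(v < 0 for v in unique.values()):
        raise ValueError("counts must be non-negative")
    if n_per_cluster < 2 and any(v > 0 for v in unique.values()):
        raise ValueError(
            "cluster-unique non-singleton SNPs need >= 2 samples per cluster"
        )
    rng = np.random.default_rng(seed)
    samples = {
        c: [f"{c}_{i}" for i in range(n_per_cluster)] for c in clusters
    }
    all_samples = [s for c in clusters for s in samples[c]]
    cols: dict[str, np.ndarray] = {}
    idx = {s: i for i, s in enumerate(all_samples)}

    def blank() -> np.ndarray:
        return np.zeros(len(all_samples), dtype=np.int8)

    snp_i = 0
    truth_members: dict[str, str] = {}
    for _ in range(shared):
        v = blank()
        for c in clusters:
            take = rng.integers(1, n_per_cluster + 1)
            for s in rng.choice(samples[c], size=take, replace=False):
                v[idx[s]] = 1
        cols[f"snp{snp_i:05d}"] = v
        truth_members[f"snp{snp_i:05d}"] = "shared"
        snp_i += 1
    for c in clusters:
        for _ in range(unique[c]):
            v = blank()
            take = rng.integers(2, n_per_cluster + 1)
            for s in rng.choice(samples[c], size=take, replace=False):
                v[idx[s]] = 1
            cols[f"snp{snp_i:05d}"] = v
            truth_members[f"snp{snp_i:05d}"] = c
            snp_i += 1
    for _ in range(singletons):
        v = blank()
        v[idx[all_samples[rng.integers(0, len(all_samples))]]] = 1
        cols[f"snp{snp_i:05d}"] = v
        truth_members[f"snp{snp_i:05d}"] = "singleton"
        snp_i += 1

    table = pd.DataFrame(cols, index=all_samples)
    assignments = pd.DataFrame(
        {
            "sample": all_samples,
            "cluster": [s.split("_")[0] for s in all_samples],
        }
    )
    truth = {
        "generator": "make_cluster_genotypes",
        "seed": seed,
        "shared": shared,
        "unique": dict(unique),
        "singletons": singletons,
        "n_per_cluster": n_per_cluster,
        "membership": truth_members,
        "clusters": clusters,
    }
    return table, {"truth": truth, "assignments": assignments}


def write_site_counts_tsv(df: pd.DataFrame, path) -> None:
    """Serialize site counts deterministically (byte-identical per seed)."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
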