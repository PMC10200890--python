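"""Patterson's D-statistic (ABBA-BABA test) with block-jackknife errors.

For a four-taxon topology (((P1, P2), P3), O), biallelic sites where the
derived allele "B" is shared by P2 and P3 form the pattern ABBA, and sites
where it is shared by P1 and P3 form BABA.  Without gene flow the two
discordant patterns arise equally often from incomplete lineage sorting;
gene flow between P3 and one ingroup taxon skews the balance.

    D = (nABBA - nBABA) / (nABBA + nBABA)

Significance comes from a delete-one block jackknife over contiguous site
blocks (robust to linkage): the standard error of D is estimated from the
leave-one-block-out replicates, Z = D / SE, and a one-sided normal p-value
is attached.  A quartet is reported significant when p < 0.01 and Z > 3.

Two counting modes: ``binary`` (one haplotype per sample, as in consensus
supercontig alignments) counts whole patterns; ``freq`` weights each site
by derived-allele frequencies, contributing (1-p1) p2 p3 (1-pO) to ABBA
and p1 (1-p2) p3 (1-pO) to BABA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SIGNIFICANCE_P = 0.01
SIGNIFICANCE_Z = 3.0
DEFAULT_BLOCK_SIZE = 2_000
MIN_BLOCKS = 20


class DStatError(ValueError):
    pass


@dataclass(frozen=True)
class QuartetSpec:
    """Sample identifiers in the topology (((P1, P2), P3), O)."""

    p1: str
    p2: str
    p3: str
    outgroup: str

    def __post_init__(self) -> None:
        if len({self.p1, self.p2, self.p3, self.outgroup}) != 4:
            raise DStatError("quartet needs four distinct samples")

    @property
    def columns(self) -> tuple[str, str, str, str]:
        return (self.p1, self.p2, self.p3, self.outgroup)


@dataclass
class DResult:
    """ABBA/BABA counts with D, jackknife Z and p for one quartet."""

    quartet: QuartetSpec
    n_abba: float
    n_baba: float
    d: float | None
    z: float | None
    p: float | None
    n_blocks: int
    block_size: int
    n_sites_used: int
    n_skipped: int
    se_zero: bool = False

    @property
    def significant(self) -> bool:
        if self.p is None:
            # constant D across blocks with D != 0: infinitely many SEs away
            return bool(self.se_zero and self.d)
        return self.p < SIGNIFICANCE_P and (self.z or 0) > SIGNIFICANCE_Z

    def to_row(self) -> dict:
        return {
            "P1": self.quartet.p1,
            "P2": self.quartet.p2,
            "P3": self.quartet.p3,
            "O": self.quartet.outgroup,
            "nABBA": self.n_abba,
            "nBABA": self.n_baba,
            "D": self.d,
            "Z": self.z,
            "p": self.p,
            "n_blocks": self.n_blocks,
            "block_size": self.block_size,
            "sites_used": self.n_sites_used,
            "sites_skipped": self.n_skipped,
            "significant": self.significant,
        }


def _site_weights(
    snp_matrix: pd.DataFrame, quartet: QuartetSpec, mode: str
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-site ABBA and BABA contributions plus the skipped-site count.

    ``binary`` mode expects 0/1 genotypes (derived-allele presence) with
    NaN for missing; sites with a derived outgroup allele are re-polarized
    against it, i.e. the outgroup defines the ancestral state.  ``freq``
    mode expects derived-allele frequencies in [0, 1].
    """
    for col in quartet.columns:
        if col not in snp_matrix.columns:
            raise DStatError(f"sample {col!r} missing from the SNP matrix")
    m = snp_matrix.loc[:, list(quartet.columns)].to_numpy(float)
    complete = ~np.isnan(m).any(axis=1)
    m = m[complete]
    skipped = int((~complete).sum())
    p1, p2, p3, po = m.T
    if mode == "binary":
        vals = m[~np.isnan(m)]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise DStatError("binary mode needs 0/1 genotypes")
        # outgroup defines the ancestral state: polarize derived = != O
        d1 = (p1 != po).astype(float)
        d2 = (p2 != po).astype(float)
        d3 = (p3 != po).astype(float)
        abba = (1 - d1) * d2 * d3
        baba = d1 * (1 - d2) * d3
    elif mode == "freq":
        abba = (1 - p1) * p2 * p3 * (1 - po)
        baba = p1 * (1 - p2) * p3 * (1 - po)
    else:
        raise DStatError(f"unknown mode {mode!r}")
    return abba, baba, skipped


def count_patterns(
    snp_matrix: pd.DataFrame, quartet: QuartetSpec, mode: str = "binary"
) -> tuple[float, float]:
    """Total (weighted) ABBA and BABA counts for one quartet."""
    abba, baba, _ = _site_weights(snp_matrix, quartet, mode)
    return float(abba.sum()), float(baba.sum())


def d_statistic(n_abba: float, n_baba: float) -> float | None:
    """D = (nABBA - nBABA) / (nABBA + nBABA); None when undefined (no
    discordant sites at all)."""
    tot = n_abba + n_baba
    if tot <= 0:
        return None
    return (n_abba - n_baba) / tot


def jackknife(
    snp_matrix: pd.DataFrame,
    quartet: QuartetSpec,
    block_size: int = DEFAULT_BLOCK_SIZE,
    mode: str = "binary",
) -> DResult:
    """D with delete-one block-jackknife Z and one-sided normal p.

    Sites are grouped into contiguous blocks of ``block_size`` in input
    order (concatenated alignment order, approximating linkage blocks);
    at least 20 non-empty blocks are required — use a smaller block size
    otherwise.  A constant D across blocks yields SE 0, flagged rather
    than divided by.
    """
    abba, baba, skipped = _site_weights(snp_matrix, quartet, mode)
    n = len(abba)
    n_blocks = int(np.ceil(n / block_size))
    if n_blocks < MIN_BLOCKS:
        raise DStatError(
            f"only {n_blocks} jackknife blocks at block_size {block_size}; "
            "use a smaller block_size"
        )
    edges = np.arange(0, n, block_size)
    abba_b = np.add.reduceat(abba, edges)
    baba_b = np.add.reduceat(baba, edges)
    tot_abba = float(abba.sum())
    tot_baba = float(baba.sum())
    d = d_statistic(tot_abba, tot_baba)
    base = DResult(
        quartet=quartet,
        n_abba=tot_abba,
        n_baba=tot_baba,
        d=d,
        z=None,
        p=None,
        n_blocks=n_blocks,
        block_size=block_size,
        n_sites_used=n,
        n_skipped=skipped,
    )
    if d is None:
        return base
    keep = (tot_abba - abba_b) + (tot_baba - baba_b) > 0
    if not keep.all():
        # a delete-one replicate with no discordant sites left: treat the
        # replicate D as the full-data D (no information lost)
        pass
    with np.errstate(invalid="ignore", divide="ignore"):
        d_j = ((tot_abba - abba_b) - (tot_baba - baba_b)) / (
            (tot_abba - abba_b) + (tot_baba - baba_b)
        )
    d_j = np.where(np.isfinite(d_j), d_j, d)
    b = len(d_j)
    var = (b - 1) / b * float(((d_j - d_j.mean()) ** 2).sum())
    se = float(np.sqrt(var))
    if se == 0.0:
        base.se_zero = True
        return base
    z = d / se
    p = float(stats.norm.sf(z))
    base.z = float(z)
    base.p = p
    return base


def run_quartets(
    snp_matrix: pd.DataFrame,
    quartets: list[QuartetSpec],
    block_size: int = DEFAULT_BLOCK_SIZE,
    mode: str = "binary",
) -> pd.DataFrame:
    """One row per quartet: counts, D, Z, p and the significance flag."""
    rows = [
        jackknife(snp_matrix, q, block_size=block_size, mode=mode).to_row()
        for q in quartets
    ]
    return pd.DataFrame(rows)


def read_quartets(path) -> list[QuartetSpec]:
    """Plain-text quartet spec: one quartet per line, four whitespace- or
    comma-separated sample names in the order P1 P2 P3 O; '#' comments."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 4:
                raise DStatError(f"quartet line needs 4 names: {line!r}")
            out.append(QuartetSpec(*parts))
    return out
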