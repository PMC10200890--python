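"""Shared and cluster-unique SNP counting, with block-level placement.

Given genotypes for samples assigned to genetic clusters (e.g. the two
intraspecific gene pools recovered by Bayesian clustering), equal numbers
of samples are drawn from each cluster, singleton SNPs (alternate allele
seen in exactly one sample of the analysis set) are removed, and every
remaining SNP is classified by the set of clusters in which its alternate
allele is observed:

* ``shared`` — observed in every cluster;
* ``unique to c`` — observed in cluster c only;
* ``mixed`` — observed in more than one but not all clusters (possible
  only with three or more clusters).

Genes carrying cluster-specific SNPs can then be placed onto block-level
chromosomes through a gene -> genomic block table and a karyotype carrying
those blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from karyoploid.karyotype import Karyotype

ADMIXTURE_THRESHOLD = 0.10


class PartitionError(ValueError):
    pass


@dataclass
class ClusterAssignment:
    """sample -> primary cluster label, with optional admixture
    proportions; a sample is flagged admixed when its minor-cluster
    proportion exceeds the 10% threshold."""

    labels: dict[str, str]
    admixture: dict[str, float] = field(default_factory=dict)
    threshold: float = ADMIXTURE_THRESHOLD

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClusterAssignment":
        """From a table with ``sample`` and ``cluster`` columns and an
        optional ``admixture`` column (minor-cluster proportion)."""
        labels = dict(zip(df["sample"], df["cluster"]))
        adm = (
            dict(zip(df["sample"], df["admixture"]))
            if "admixture" in df.columns
            else {}
        )
        return cls(labels=labels, admixture=adm)

    def is_admixed(self, sample: str) -> bool:
        return self.admixture.get(sample, 0.0) > self.threshold

    def clusters(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def members(self, cluster: str, exclude_admixed: bool = False) -> list[str]:
        out = [s for s, c in self.labels.items() if c == cluster]
        if exclude_admixed:
            out = [s for s in out if not self.is_admixed(s)]
        return out


@dataclass
class ClusterSNPPartition:
    """Outcome of the shared/unique partition."""

    shared: set
    unique_per_cluster: dict[str, set]
    mixed: set
    singletons_removed: int
    absent: int  # SNPs with no alternate allele in the subsample
    subsample: dict[str, list]

    def counts(self) -> dict:
        out = {"shared": len(self.shared)}
        out.update({c: len(v) for c, v in self.unique_per_cluster.items()})
        out["mixed"] = len(self.mixed)
        out["singletons_removed"] = self.singletons_removed
        return out


def partition_snps(
    genotypes: pd.DataFrame,
    clusters: ClusterAssignment,
    n_per_cluster: int = 6,
    seed: int = 0,
    exclude_admixed: bool = False,
) -> ClusterSNPPartition:
    """Count SNPs shared between and unique to clusters.

    ``genotypes`` is a samples x SNPs table of alternate-allele presence
    (0/1; any positive dosage counts as presence).  ``n_per_cluster``
    samples are drawn from each cluster with the given seed, singletons
    (alternate allele in exactly one drawn sample) are removed, and each
    remaining SNP is assigned by the clusters its alternate allele is seen
    in.  Identical seeds give identical partitions.
    """
    labels = clusters.clusters()
    if len(labels) < 2:
        raise PartitionError("need at least two clusters")
    rng = np.random.default_rng(seed)
    chosen: dict[str, list] = {}
    for c in labels:
        members = [
            s for s in clusters.members(c, exclude_admixed)
            if s in genotypes.index
        ]
        if len(members) < n_per_cluster:
            raise PartitionError(
                f"cluster {c!r} has {len(members)} usable samples, "
                f"need {n_per_cluster}"
            )
        chosen[c] = sorted(rng.choice(members, n_per_cluster, replace=False))

    all_chosen = [s for c in labels for s in chosen[c]]
    sub = (genotypes.loc[all_chosen] > 0).astype(int)
    carriers = sub.sum(axis=0)
    singleton_mask = carriers == 1
    absent_mask = carriers == 0
    kept = sub.loc[:, ~(singleton_mask | absent_mask)]

    presence = pd.DataFrame(
        {c: kept.loc[chosen[c]].any(axis=0) for c in labels}
    )
    n_in = presence.sum(axis=1)
    shared = set(presence.index[n_in == len(labels)])
    unique = {
        c: set(presence.index[presence[c] & (n_in == 1)]) for c in labels
    }
    mixed = set(presence.index[(n_in > 1) & (n_in < len(labels))])
    return ClusterSNPPartition(
        shared=shared,
        unique_per_cluster=unique,
        mixed=mixed,
        singletons_removed=int(singleton_mask.sum()),
        absent=int(absent_mask.sum()),
        subsample=chosen,
    )


# ---------------------------------------------------------------------------
# block-level placement
# ---------------------------------------------------------------------------


def load_gene_block_table(path) -> dict[str, str]:
    """gene -> genomic block TSV (columns ``gene``, ``block``); a gene
    maps to at most one block."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "block"} <= set(df.columns):
        raise PartitionError("gene table needs 'gene' and 'block' columns")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise PartitionError(f"gene {dup!r} mapped to more than one block")
    return dict(zip(df["gene"], df["block"]))


def place_on_blocks(
    snp_genes: dict[str, str],
    gene_table: dict[str, str],
    karyotype: Karyotype,
    unrearranged_only: bool = False,
    reference: Karyotype | None = None,
) -> pd.DataFrame:
    """Place SNP-carrying genes onto chromosomes via their genomic block.

    ``snp_genes`` maps SNP id -> gene id.  Each gene is placed on every
    chromosome of ``karyotype`` carrying (part of) its block.  With
    ``unrearranged_only`` (and a ``reference`` complement), placements on
    chromosomes whose structure differs from the reference are flagged
    ``rearranged`` instead of placed — the display simplification of
    showing SNPs only on chromosomes without species-specific
    rearrangements.  Genes absent from the table are listed unplaced.
    """
    from karyoploid.karyotype import canonical_form

    ref_keys = None
    if unrearranged_only:
        if reference is None:
            raise PartitionError("unrearranged_only needs a reference karyotype")
        ref_keys = {canonical_form(c) for c in reference.chromosomes}
    block_chroms: dict[str, list[tuple[str, bool]]] = {}
    for chrom in karyotype.chromosomes:
        unrearranged = (
            ref_keys is None or canonical_form(chrom) in ref_keys
        )
        for s in chrom.segments:
            lst = block_chroms.setdefault(s.block, [])
            if (chrom.name, unrearranged) not in lst:
                lst.append((chrom.name, unrearranged))
    rows = []
    for snp, gene in sorted(snp_genes.items()):
        block = gene_table.get(gene)
        if block is None:
            rows.append(
                {"snp": snp, "gene": gene, "block": None, "chromosome": None,
                 "status": "unplaced"}
            )
            continue
        for chrom_name, unre in block_chroms.get(block, []):
            status = "placed"
            if unrearranged_only and not unre:
                status = "rearranged"
            rows.append(
                {"snp": snp, "gene": gene, "block": block,
                 "chromosome": chrom_name, "status": status}
            )
        if block not in block_chroms:
            rows.append(
                {"snp": snp, "gene": gene, "block": block, "chromosome": None,
                 "status": "block_absent"}
            )
    return pd.DataFrame(
        rows, columns=["snp", "gene", "block", "chromosome", "status"]
    )
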