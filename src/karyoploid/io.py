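"""File formats, run configuration and the multi-stage pipeline runner.

VCF reading is deliberately minimal: biallelic SNP records are streamed in
contig/position order (the order matters downstream, where jackknife
blocks are contiguous site runs), multiallelic and non-SNP records are
skipped with counts, and missing FORMAT fields requested by a caller are
reported by name.  Coordinates follow VCF (1-based); block fractions used
by the karyotype layer are half-open [start, end).

A pipeline run executes the requested stages (karyotype replay/summary,
ploidy inference, D-statistics, SNP partitioning) under one global seed
from which per-stage seeds are derived by stage-name hashing, and writes a
manifest capturing the configuration, package version and input checksums
so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("karyoploid")


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------


def read_vcf_minimal(path, require: tuple[str, ...] = ()):
    """Stream biallelic SNP records from a VCF (plain or bgzipped).

    Yields ``cyvcf2.Variant`` objects in file order; multiallelic or
    non-SNP records are skipped and counted in the ``stats`` dict attached
    to the generator's ``send``-free protocol — use
    :func:`read_vcf_records` for a materialized (records, stats) pair.
    ``require`` names FORMAT fields that must be declared in the header;
    a missing one raises a :class:`FormatError` naming it.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    for field in require:
        if not vcf.contains(field):
            raise FormatError(
                f"VCF {path} lacks required FORMAT field {field!r}"
            )
    for rec in vcf:
        if len(rec.ALT) != 1:
            yield None  # multiallelic marker; callers count and skip
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            yield None
            continue
        yield rec


def read_vcf_records(path, require: tuple[str, ...] = ()):
    """Materialized biallelic SNP records: (list of variants, stats)."""
    records, skipped = [], 0
    for rec in read_vcf_minimal(path, require):
        if rec is None:
            skipped += 1
        else:
            records.append(rec)
    stats = {"biallelic_snps": len(records), "skipped_non_biallelic": skipped}
    logger.info("VCF %s: %d biallelic SNPs, %d records skipped",
                path, len(records), skipped)
    return records, stats


def read_genotype_matrix(path) -> tuple[pd.DataFrame, dict]:
    """Alternate-allele presence matrix (sites x samples) from VCF GTs.

    Values: 1 when the sample carries at least one alternate allele, 0
    when homozygous reference, NaN when missing.  Site order is preserved.
    """
    from cyvcf2 import VCF

    samples = VCF(str(path)).samples
    rows, index = [], []
    records, stats = read_vcf_records(path, require=("GT",))
    for rec in records:
        gts = rec.genotype.array()
        alleles = gts[:, :-1]
        has_alt = (alleles > 0).any(axis=1)
        missing = (alleles < 0).all(axis=1)
        row = has_alt.astype(float)
        row[missing] = np.nan
        rows.append(row)
        index.append(f"{rec.CHROM}:{rec.POS}")
    df = pd.DataFrame(rows, columns=samples, index=index)
    return df, stats


def read_allele_depths(path, sample: str | None = None) -> pd.DataFrame:
    """Per-site (ref_reads, alt_reads) for one sample from VCF AD fields."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if not vcf.contains("AD"):
        raise FormatError(f"VCF {path} lacks required FORMAT field 'AD'")
    samples = vcf.samples
    if sample is None:
        if len(samples) != 1:
            raise FormatError(
                f"VCF has {len(samples)} samples; pass sample=..."
            )
        sample = samples[0]
    if sample not in samples:
        raise FormatError(f"sample {sample!r} not in VCF ({samples})")
    si = samples.index(sample)
    rows = []
    records, _stats = read_vcf_records(path)
    for rec in records:
        ad = rec.format("AD")
        if ad is None:
            continue
        ref, alt = int(ad[si][0]), int(ad[si][1])
        if ref < 0 or alt < 0:
            continue  # missing
        rows.append((f"{rec.CHROM}:{rec.POS}", ref, alt))
    return pd.DataFrame(rows, columns=["site_id", "ref_reads", "alt_reads"])


def write_vcf_minimal(genotypes: pd.DataFrame, path, contig: str = "1") -> None:
    """Write a presence/absence genotype table (samples x SNPs) as a
    minimal single-contig VCF with GT fields (haploid-style 0 / 1 calls);
    deterministic output for fixture generation."""
    samples = list(genotypes.index)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for pos0, snp in enumerate(genotypes.columns):
        gts = "\t".join(str(int(v)) for v in genotypes[snp])
        lines.append(
            f"{contig}\t{pos0 + 1}\t{snp}\tA\tT\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed by stage-name hashing,
    so stages are independently reproducible."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


STAGES = ("replay", "ploidy", "dstat", "snp_partition")


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the configured stages and write a manifest.

    ``config`` keys: ``seed`` (global), and one block per stage to run
    (``replay``, ``ploidy``, ``dstat``, ``snp_partition``).  All referenced
    input files are checked before any stage runs; a stage failure aborts
    with the stage name.  Outputs land in ``out_dir`` and are reproducible
    under a fixed seed.
    """
    import karyoploid
    from karyoploid import dstat as dmod
    from karyoploid import karyotype as km
    from karyoploid import ploidy as pmod
    from karyoploid import snp_partition as spmod

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    requested = [s for s in STAGES if s in config]
    if not requested:
        raise FormatError("config requests no stages")

    # fail fast: every referenced input must exist before any stage runs
    input_paths = []
    for s in requested:
        for key, val in config[s].items():
            if key.endswith(("file", "path", "input", "vcf", "table",
                             "scenario", "clusters", "quartets", "reference")):
                if isinstance(val, str) and val != "packaged":
                    if not Path(val).exists():
                        raise FormatError(
                            f"stage {s!r}: input file {val!r} not found"
                        )
                    input_paths.append(val)

    manifest: dict = {
        "package": "karyoploid",
        "version": karyoploid.__version__,
        "seed": seed,
        "config": config,
        "inputs": {p: sha256_file(p) for p in sorted(set(input_paths))},
        "stages": [],
        "outputs": {},
    }

    def record(stage, name, path):
        manifest["outputs"][f"{stage}/{name}"] = str(path)

    for stage in requested:
        cfg = config[stage]
        logger.info("stage %s starting", stage)
        try:
            if stage == "replay":
                scen = (
                    km.catolobus_scenario()
                    if cfg.get("scenario", "packaged") == "packaged"
                    else km.scenario_from_json(Path(cfg["scenario"]).read_text())
                )
                final, snaps = km.replay(scen)
                kpath = out / "karyotype.json"
                kpath.write_text(km.karyotype_to_json(final) + "\n")
                record(stage, "karyotype", kpath)
                reference = km.apply_wgd(km.build_ack())
                summ = km.summarize(final, reference)
                spath = out / "karyotype_summary.json"
                spath.write_text(json.dumps(summ, indent=1, sort_keys=True))
                record(stage, "summary", spath)
            elif stage == "ploidy":
                sites, log = pmod.load_site_counts(
                    cfg["input"],
                    sample=cfg.get("sample"),
                    min_coverage=cfg.get("min_coverage",
                                         pmod.DEFAULT_MIN_COVERAGE),
                    min_minor_reads=cfg.get("min_minor_reads",
                                            pmod.DEFAULT_MIN_MINOR_READS),
                )
                rpt = pmod.ploidy_fit_report(
                    sites,
                    sample=cfg.get("sample", "sample"),
                    seed=stage_seed(seed, stage),
                    denoise=cfg.get("denoise", False),
                )
                obj = rpt.to_dict()
                obj["filter_log"] = log
                ppath = out / "ploidy_report.json"
                ppath.write_text(json.dumps(obj, indent=1, sort_keys=True))
                record(stage, "report", ppath)
                if cfg.get("plot", False):
                    gpath = out / "ploidy_histogram.png"
                    pmod.plot_frequency_histogram(
                        pmod.alt_frequencies(sites), None, gpath
                    )
                    record(stage, "plot", gpath)
            elif stage == "dstat":
                inp = cfg["input"]
                if str(inp).endswith((".vcf", ".vcf.gz")):
                    matrix, _stats = read_genotype_matrix(inp)
                else:
                    matrix = pd.read_csv(inp, sep="\t", index_col=0)
                quartets = dmod.read_quartets(cfg["quartets"])
                table = dmod.run_quartets(
                    matrix,
                    quartets,
                    block_size=cfg.get("block_size", dmod.DEFAULT_BLOCK_SIZE),
                    mode=cfg.get("mode", "binary"),
                )
                dpath = out / "dstat.tsv"
                table.to_csv(dpath, sep="\t", index=False,
                             lineterminator="\n")
                record(stage, "table", dpath)
            elif stage == "snp_partition":
                inp = cfg["vcf"]
                if str(inp).endswith((".vcf", ".vcf.gz")):
                    matrix, _stats = read_genotype_matrix(inp)
                    genotypes = matrix.T.fillna(0)
                else:
                    genotypes = pd.read_csv(inp, sep="\t", index_col=0)
                clusters = spmod.ClusterAssignment.from_frame(
                    pd.read_csv(cfg["clusters"], sep="\t")
                )
                part = spmod.partition_snps(
                    genotypes,
                    clusters,
                    n_per_cluster=cfg.get("n_per_cluster", 6),
                    seed=stage_seed(seed, stage),
                )
                cpath = out / "snp_partition.json"
                cpath.write_text(
                    json.dumps(part.counts(), indent=1, sort_keys=True)
                )
                record(stage, "counts", cpath)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append(stage)
        logger.info("stage %s done", stage)

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
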