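"""Seeded generators for every input the pipeline consumes.

The simulations encode the statistical structure the pipeline assumes:
transcripts expressed on the sense strand with a small uniform antisense
bleed-through, window-localised antisense transcription units that multiply
the antisense:sense odds by 2^enrichment, multi-sample POLR2A peak
presence/absence at antisense promoters versus background, and
two-condition proximal/distal poly(A) counts with a specified usage shift.

Every generator draws from its own stream derived from the master seed by
a fixed offset, so outputs are fully deterministic given the seed and any
subset of generators can be re-run independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from iris.apa import SiteCountTable
from iris.genomic_io import (
    NARROWPEAK_COLUMNS,
    PeakSet,
    TranscriptModel,
    blocks_to_str,
)

# fixed sub-stream offsets from the master seed
_STREAMS = {
    "transcriptome": 1,
    "units": 2,
    "groseq": 3,
    "rnaseq": 4,
    "chip": 5,
    "apa": 6,
}


@dataclass
class SimConfig:
    """Study conditions for the simulations.

    Defaults describe the benchmark scenario: 200 single-isoform genes,
    30 antisense units of log2 odds enrichment 2.5, 67 ChIP samples with
    peak presence 0.8 at true antisense promoters and 0.1 at background,
    and a 0.7/0.3 -> 0.4/0.6 proximal/distal poly(A) usage shift counted in
    two 500-read replicate libraries per condition.
    """

    n_genes: int = 200
    length_range: tuple[int, int] = (1500, 4000)
    mean_reads: float = 2000.0  # sense reads per transcript (Poisson)
    antisense_noise_rate: float = 0.05  # uniform bleed-through probability
    n_units: int = 30
    unit_log2_enrichment: float = 2.5
    unit_length_range: tuple[int, int] = (500, 1000)
    antisense_units: list[tuple[str, int, int, float]] | None = None
    read_length: int = 50
    n_chip_samples: int = 67
    p_peak_true: float = 0.8
    p_peak_bg: float = 0.1
    peak_width: int = 300
    peak_offset: int = 500  # peak centre this far 5' of the antisense start
    apa_n_genes: int = 1
    apa_usage: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {"A": (0.7, 0.3), "B": (0.4, 0.6)}
    )
    apa_reads: int = 500  # reads per replicate library
    apa_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.antisense_noise_rate, self.p_peak_true, self.p_peak_bg):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.n_chip_samples < 1:
            raise ValueError("n_chip_samples must be >= 1")
        for cond, usage in self.apa_usage.items():
            if abs(sum(usage) - 1.0) > 1e-9:
                raise ValueError(f"usage vector for {cond} must sum to 1")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["apa_usage"] = {k: list(v) for k, v in self.apa_usage.items()}
        return out


def simulate_transcriptome(config: SimConfig) -> dict[str, TranscriptModel]:
    """Single-isoform gene models with 1-5 exons, placed without overlap.

    Genes are laid out round-robin on ten synthetic chromosomes with 10-kb
    gaps; intron sizes are 200-2000 nt; cds_length is a uniform fraction of
    the transcript.  Deterministic given the seed.
    """
    rng = config.rng("transcriptome")
    lo, hi = config.length_range
    cursors: dict[str, int] = {}
    models: dict[str, TranscriptModel] = {}
    for i in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        n_exons = int(rng.integers(1, 6))
        if n_exons > 1:
            cuts = np.sort(rng.choice(np.arange(1, length), size=n_exons - 1, replace=False))
            widths = np.diff(np.concatenate([[0], cuts, [length]]))
        else:
            widths = np.array([length])
        chrom = f"chr{i % 10 + 1}"
        pos = cursors.get(chrom, 10_000)
        exons = []
        for j, w in enumerate(widths):
            exons.append((pos, pos + int(w)))
            pos += int(w)
            if j < len(widths) - 1:
                pos += int(rng.integers(200, 2001))
        cursors[chrom] = pos + 10_000
        strand = "+" if rng.random() < 0.5 else "-"
        cds = int(rng.uniform(0.2, 0.8) * length)
        tid = f"TX{i:04d}"
        models[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=f"G{i:04d}",
            chrom=chrom,
            genome_strand=strand,
            exons=tuple(exons),
            cds_length=cds,
        )
    return models


def place_antisense_units(
    models: Mapping[str, TranscriptModel], config: SimConfig
) -> list[tuple[str, int, int, float]]:
    """Declare antisense units: (transcript_id, start, end, log2 enrichment)."""
    if config.antisense_units is not None:
        return list(config.antisense_units)
    rng = config.rng("units")
    tids = sorted(models)
    chosen = rng.choice(len(tids), size=min(config.n_units, len(tids)), replace=False)
    units = []
    for idx in sorted(chosen):
        tid = tids[idx]
        length = models[tid].length
        ulo, uhi = config.unit_length_range
        ulen = int(rng.integers(ulo, uhi + 1))
        ulen = min(ulen, length)
        start = int(rng.integers(0, length - ulen + 1))
        units.append((tid, start, start + ulen, float(config.unit_log2_enrichment)))
    return units


def simulate_stranded_reads(
    models: Mapping[str, TranscriptModel],
    config: SimConfig,
    library: str = "groseq",
    units: Sequence[tuple[str, int, int, float]] | None = None,
) -> pd.DataFrame:
    """Stranded reads against the representative transcriptome.

    Per transcript, Poisson(mean_reads) reads with uniform 5' positions; a
    read is flipped to antisense with probability ``antisense_noise_rate``,
    except inside a declared unit where the antisense:sense *odds* are
    multiplied by 2^enrichment (so the in-unit/out-of-unit odds ratio equals
    the declared enrichment exactly in expectation).  Read length is fixed
    and clipped at the transcript bounds.
    """
    if library not in ("groseq", "rnaseq"):
        raise ValueError("library must be 'groseq' or 'rnaseq'")
    rng = config.rng(library)
    unit_map: dict[str, list[tuple[int, int, float]]] = {}
    for tid, ustart, uend, enr in units or []:
        unit_map.setdefault(tid, []).append((ustart, uend, enr))
    noise = config.antisense_noise_rate
    base_odds = noise / (1.0 - noise) if noise < 1.0 else np.inf
    rl = config.read_length
    frames = []
    for tid in sorted(models):
        length = models[tid].length
        n = int(rng.poisson(config.mean_reads))
        if n == 0:
            continue
        pos = rng.integers(0, length, size=n)
        p_flip = np.full(n, noise)
        for ustart, uend, enr in unit_map.get(tid, []):
            in_unit = (pos >= ustart) & (pos < uend)
            odds = base_odds * 2.0 ** enr
            p_flip[in_unit] = odds / (1.0 + odds)
        anti = rng.random(n) < p_flip
        starts = np.where(anti, np.maximum(0, pos - rl + 1), pos)
        ends = np.where(anti, pos + 1, np.minimum(length, pos + rl))
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": tid,
                    "start": starts.astype(np.int64),
                    "end": ends.astype(np.int64),
                    "strand": np.where(anti, "antisense", "sense"),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["transcript_id", "start", "end", "strand"])
    return pd.concat(frames, ignore_index=True)


def _unit_loci_frame(
    models: Mapping[str, TranscriptModel],
    units: Sequence[tuple[str, int, int, float]],
) -> pd.DataFrame:
    rows = []
    for tid, start, end, enr in units:
        model = models[tid]
        blocks = model.project_to_genome(start, end)
        rows.append(
            {
                "transcript_id": tid,
                "start": start,
                "end": end,
                "enrichment": enr,
                "chrom": model.chrom,
                "blocks": blocks_to_str(blocks),
                "genome_strand": model.antisense_strand,
                "name": f"{tid}:{start}-{end}",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "start", "end", "enrichment",
            "chrom", "blocks", "genome_strand", "name",
        ],
    )


def simulate_chip_samples(
    true_loci: pd.DataFrame,
    background_loci: pd.DataFrame,
    config: SimConfig,
) -> list[PeakSet]:
    """Multi-sample narrowPeak calls.

    Each sample emits a peak of ``peak_width`` centred ``peak_offset`` bp
    upstream (strand-aware) of each true locus with probability
    ``p_peak_true``, and of each background locus with probability
    ``p_peak_bg``.  Loci frames need chrom / blocks / genome_strand columns.
    """
    rng = config.rng("chip")
    centres = []
    for frame, p in ((true_loci, config.p_peak_true), (background_loci, config.p_peak_bg)):
        for _, row in frame.iterrows():
            blocks = row["blocks"]
            if isinstance(blocks, str):
                from iris.genomic_io import str_to_blocks

                blocks = str_to_blocks(blocks)
            blocks = sorted(blocks)
            if row["genome_strand"] == "+":
                centre = blocks[0][0] - config.peak_offset
            else:
                centre = blocks[-1][1] + config.peak_offset
            centres.append((str(row["chrom"]), int(centre), float(p)))
    half = config.peak_width // 2
    peak_sets = []
    for s in range(config.n_chip_samples):
        rows = []
        for k, (chrom, centre, p) in enumerate(centres):
            if rng.random() >= p:
                continue
            jitter = int(rng.integers(-100, 101))
            start = max(0, centre + jitter - half)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + config.peak_width,
                    "name": f"peak_{s}_{k}",
                    "score": int(rng.integers(100, 1001)),
                    "strand": ".",
                    "signal_value": round(float(rng.uniform(2, 12)), 3),
                    "p_value": round(float(rng.uniform(3, 12)), 3),
                    "q_value": round(float(rng.uniform(2, 9)), 3),
                    "summit": half,
                }
            )
        peaks = pd.DataFrame(rows, columns=NARROWPEAK_COLUMNS)
        peak_sets.append(PeakSet(sample_id=f"sample{s:02d}", peaks=peaks))
    return peak_sets


def simulate_apa_counts(config: SimConfig) -> list[SiteCountTable]:
    """Multinomial poly(A)-site counts per condition.

    Per gene and condition, ``apa_replicates`` libraries of ``apa_reads``
    reads each are drawn from the condition's usage vector and summed
    (replicates are not modelled as random effects downstream).
    """
    rng = config.rng("apa")
    n_sites = {len(u) for u in config.apa_usage.values()}
    if len(n_sites) != 1:
        raise ValueError("all usage vectors must have the same number of sites")
    k = n_sites.pop()
    site_ids = tuple(f"pA{i + 1}" for i in range(k))
    positions = tuple(1000 + 400 * i for i in range(k))
    tables = []
    for g in range(config.apa_n_genes):
        data = {}
        for cond, usage in config.apa_usage.items():
            total = np.zeros(k, dtype=np.int64)
            for _ in range(config.apa_replicates):
                total += rng.multinomial(config.apa_reads, np.asarray(usage, dtype=float))
            data[cond] = total
        counts = pd.DataFrame(data, index=list(site_ids))
        tables.append(
            SiteCountTable(
                gene_id=f"APA{g:03d}", site_ids=site_ids, positions=positions, counts=counts
            )
        )
    return tables


def write_gtf(models: Mapping[str, TranscriptModel], path: str | Path) -> None:
    """Deterministic GTF 2.2 with transcript, exon and CDS features."""
    with open(path, "w") as handle:
        for tid in sorted(models):
            m = models[tid]
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            span = (m.exons[0][0] + 1, m.exons[-1][1])
            handle.write(
                "\t".join(
                    [m.chrom, "sim", "transcript", str(span[0]), str(span[1]),
                     ".", m.genome_strand, ".", attrs]
                )
                + "\n"
            )
            for s, e in m.exons:
                handle.write(
                    "\t".join(
                        [m.chrom, "sim", "exon", str(s + 1), str(e), ".",
                         m.genome_strand, ".", attrs]
                    )
                    + "\n"
                )
            if m.cds_length > 0:
                for s, e in m.project_to_genome(0, m.cds_length):
                    handle.write(
                        "\t".join(
                            [m.chrom, "sim", "CDS", str(s + 1), str(e), ".",
                             m.genome_strand, "0", attrs]
                        )
                        + "\n"
                    )


def write_simulation(config: SimConfig, outdir: str | Path) -> dict[str, object]:
    """Generate and persist a full simulated study.

    Writes annotation.gtf, groseq.tsv / rnaseq.tsv read tables, a chip/
    directory of narrowPeak files, apa_counts.tsv and truth.tsv (the
    declared antisense units with genomic projections).  Returns the
    in-memory objects for direct use.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    models = simulate_transcriptome(config)
    units = place_antisense_units(models, config)
    truth = _unit_loci_frame(models, units)
    groseq = simulate_stranded_reads(models, config, "groseq", units)
    rnaseq = simulate_stranded_reads(models, config, "rnaseq", units)

    write_gtf(models, outdir / "annotation.gtf")
    for name, frame in (("groseq", groseq), ("rnaseq", rnaseq)):
        frame.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    # ChIP peaks: true antisense promoters at the declared units; spurious
    # background presence at a deterministic region of every unit-free gene
    unit_tids = {u[0] for u in units}
    bg_rows = []
    for tid in sorted(models):
        if tid in unit_tids:
            continue
        length = models[tid].length
        bg_rows.append({"transcript_id": tid, "start": 0, "end": min(2000, length)})
    background = _unit_loci_frame(
        models, [(r["transcript_id"], r["start"], r["end"], 0.0) for r in bg_rows]
    )
    chip_dir = outdir / "chip"
    chip_dir.mkdir(exist_ok=True)
    peak_sets = simulate_chip_samples(truth, background, config)
    from iris.genomic_io import write_narrowpeak

    for ps in peak_sets:
        write_narrowpeak(ps, chip_dir / f"{ps.sample_id}.narrowPeak")

    apa_tables = simulate_apa_counts(config)
    rows = []
    for table in apa_tables:
        for site, posn in zip(table.site_ids, table.positions):
            for cond in table.conditions:
                rows.append(
                    {
                        "gene": table.gene_id,
                        "site": site,
                        "position": posn,
                        "condition": cond,
                        "count": int(table.counts.loc[site, cond]),
                    }
                )
    pd.DataFrame(rows).to_csv(outdir / "apa_counts.tsv", sep="\t", index=False)

    return {
        "models": models,
        "units": units,
        "truth": truth,
        "groseq": groseq,
        "rnaseq": rnaseq,
        "peak_sets": peak_sets,
        "apa_tables": apa_tables,
    }
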