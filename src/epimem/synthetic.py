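"""Synthetic cohort generator for the epigenetic-memory pipeline.

Emulates the data shapes the analysis consumes, with the cohort design of
the study it models: two iPSC groups of different cell of origin (PTC,
proximal tubule; TTF, tail-tip fibroblast), two lines per group and two
ChIP replicates per line; three histone marks plus an input channel per
chromatin prep; two animal replicates per group for nanopore methylation;
and a qPCR panel with four lines per group, three wells per line, plus an
embryonic-kidney-like calibrator group.

Peaks sit at the TSSs of "active" genes with Poisson read counts over a
uniform Poisson background that the input channel shares; per-CpG
methylation is beta-binomial with a hypomethylated valley within +/-1 kb
of each TSS, as seen at key genes in pluripotent stem cells. A tunable
"memory effect" — the quantity the pipeline exists to detect — boosts the
ChIP signal (or deepens/shallows the methylation valley) for the genes of
chosen target sets in one group only. All outputs are deterministic under
a fixed seed, and every generated table passes the package's readers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .annotation import GeneAnnotation, GeneSet, GenomicInterval
from .chip_quant import MARKS

READ_LEN = 50

#: 18 organ/system development stand-in gene sets with germ layers
DEFAULT_SET_LAYOUT = (
    ("kidney_dev", "mesoderm"),
    ("heart_dev", "mesoderm"),
    ("muscle_dev", "mesoderm"),
    ("blood_vessel_dev", "mesoderm"),
    ("bone_dev", "mesoderm"),
    ("urogenital_dev", "mesoderm"),
    ("liver_dev", "endoderm"),
    ("lung_dev", "endoderm"),
    ("pancreas_dev", "endoderm"),
    ("gut_dev", "endoderm"),
    ("thyroid_dev", "endoderm"),
    ("thymus_dev", "endoderm"),
    ("brain_dev", "ectoderm"),
    ("spinal_cord_dev", "ectoderm"),
    ("skin_dev", "ectoderm"),
    ("eye_dev", "ectoderm"),
    ("ear_dev", "ectoderm"),
    ("neural_crest_dev", "ectoderm"),
)

#: renal-development panel assayed by qPCR after differentiation
DEFAULT_QPCR_PANEL = (
    "Osr1", "Cited1", "Six2", "Sall1", "Wt1", "Pax2", "Gata3",
    "Jag1", "Hoxb7", "Cret", "Cdh6", "Cd34", "Foxd1", "Pbx1",
)


@dataclass(frozen=True)
class MemoryEffect:
    """Cell-of-origin signal injected into target gene sets of one group.

    For a histone-mark assay, the Poisson ChIP signal mean at target-set
    genes is multiplied by (1 + effect_size) in ``group``. For the 'meth'
    assay, effect_size is an additive increase in the TSS valley depth
    (clipped to [0, 1]) — i.e. extra TSS hypomethylation in ``group``.
    """

    target_sets: tuple = ("kidney_dev",)
    assay: str = "H3K4me3"
    effect_size: float = 0.0
    group: str = "PTC"


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort. Defaults are the study design."""

    seed: int = 0
    n_chrom: int = 2
    genes_per_chrom: int = 120
    gene_spacing_bp: int = 20_000
    groups: tuple = ("PTC", "TTF")
    lines_per_group: int = 2
    replicates_per_line: int = 2
    marks: tuple = MARKS
    library_size_mean: int = 5_000_000
    signal_reads_per_peak: float = 75.0
    signal_lognorm_sigma: float = 0.3
    peak_width_mean: int = 1000
    active_prob: float = 0.85
    background_rate: float = 1.0  # background reads per kb of genome
    # methylation landscape
    meth_replicates_per_group: int = 2
    cpg_density: float = 10.0  # CpG motifs per kb
    meth_coverage_mean: float = 30.0
    meth_base_mean: float = 0.75
    meth_site_sigma: float = 0.5  # shared per-site logit spread
    meth_sample_sigma: float = 0.2  # per-sample logit wobble
    tss_valley_depth: float = 0.5
    # gene sets
    n_gene_sets: int = 18
    genes_per_set: int = 12
    # injected memory signal
    memory_effect: MemoryEffect = field(default_factory=MemoryEffect)
    # qPCR layer
    qpcr_genes: tuple = DEFAULT_QPCR_PANEL
    qpcr_fold_changes: dict = field(default_factory=dict)  # gene -> fold in PTC
    qpcr_lines_per_group: int = 4
    qpcr_wells_per_line: int = 3
    qpcr_noise_sd: float = 0.25  # per-well Ct noise (cycles)
    qpcr_ipsc_delta_ct: float = 5.0  # extra dCt in iPSC groups vs calibrator
    qpcr_calibrator_group: str = "E13.5_kidney"

    @property
    def chrom_len(self) -> int:
        return self.genes_per_chrom * self.gene_spacing_bp

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def validate(self) -> None:
        for name in (
            "n_chrom", "genes_per_chrom", "gene_spacing_bp", "lines_per_group",
            "replicates_per_line", "library_size_mean", "peak_width_mean",
            "n_gene_sets", "genes_per_set", "meth_replicates_per_group",
            "qpcr_lines_per_group", "qpcr_wells_per_line",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimConfig.{name} must be positive")
        if self.memory_effect.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_gene_sets > len(DEFAULT_SET_LAYOUT):
            raise ValueError(
                f"at most {len(DEFAULT_SET_LAYOUT)} gene sets supported"
            )
        if self.n_gene_sets * self.genes_per_set > self.n_chrom * self.genes_per_chrom:
            raise ValueError("gene sets need more genes than the genome holds")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "memory_effect" in d and isinstance(d["memory_effect"], dict):
            me = dict(d["memory_effect"])
            if "target_sets" in me:
                me["target_sets"] = tuple(me["target_sets"])
            d["memory_effect"] = MemoryEffect(**me)
        elif d.get("memory_effect") is None:
            d["memory_effect"] = MemoryEffect(effect_size=0.0)
        for key in ("groups", "marks", "qpcr_genes"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = list(self.groups)
        d["marks"] = list(self.marks)
        d["qpcr_genes"] = list(self.qpcr_genes)
        d["memory_effect"]["target_sets"] = list(self.memory_effect.target_sets)
        return d


@dataclass
class SimSample:
    """One simulated sequencing library with its called peaks."""

    sample_id: str
    group: str
    line_id: str
    replicate: int
    mark: str
    peaks: list  # GenomicInterval; empty for input samples
    reads: pd.DataFrame  # columns chrom, start, end
    library_size: int


# ---------------------------------------------------------------------------
# annotation + gene sets


def generate_annotation(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[GeneAnnotation], list[GeneSet]]:
    """Evenly spaced genes with random strand, plus gene-set stand-ins.

    Spacing must exceed the widest TSS window span so windows never
    collide (scores stay attributable to one gene).
    """
    cfg.validate()
    if cfg.gene_spacing_bp < 5000 + 2 * READ_LEN:
        raise ValueError(
            "gene_spacing_bp smaller than the TSS-window span would make "
            "TSS windows collide"
        )
    genes: list[GeneAnnotation] = []
    body_len = min(2000, cfg.gene_spacing_bp // 4)
    k = 0
    for chrom in cfg.chrom_names:
        for i in range(cfg.genes_per_chrom):
            tss = i * cfg.gene_spacing_bp + cfg.gene_spacing_bp // 2
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"G{k:04d}"
            if strand == "+":
                start, end = tss, tss + body_len
            else:
                start, end = tss + 1 - body_len, tss + 1
            genes.append(
                GeneAnnotation.from_body(gene_id, gene_id, chrom, strand, start, end)
            )
            k += 1
    order = rng.permutation(len(genes))
    gene_sets = []
    for s in range(cfg.n_gene_sets):
        name, layer = DEFAULT_SET_LAYOUT[s]
        members = frozenset(
            genes[j].symbol.upper()
            for j in order[s * cfg.genes_per_set : (s + 1) * cfg.genes_per_set]
        )
        gene_sets.append(GeneSet(name, layer, members))
    return genes, gene_sets


def _target_gene_mask(
    genes: list[GeneAnnotation], gene_sets: list[GeneSet], effect: MemoryEffect
) -> np.ndarray:
    targets = set()
    by_name = {gs.name: gs for gs in gene_sets}
    for name in effect.target_sets:
        if name not in by_name:
            raise ValueError(f"memory_effect targets unknown gene set {name!r}")
        targets |= set(by_name[name].members)
    return np.array([g.symbol.upper() in targets for g in genes])


# ---------------------------------------------------------------------------
# ChIP channel


def generate_chip(
    cfg: SimConfig,
    genes: list[GeneAnnotation],
    gene_sets: list[GeneSet],
    rng: np.random.Generator,
) -> tuple[list[SimSample], dict]:
    """Simulated ChIP libraries: peaks at active TSSs, Poisson counts,
    shared uniform background, one input library per chromatin prep.

    Returns (samples, truth); truth carries the realized per-gene expected
    signal and the expected background-adjusted RPKM per (mark, group),
    against which parameter recovery is checked.
    """
    cfg.validate()
    n_genes = len(genes)
    effect = cfg.memory_effect
    target = _target_gene_mask(genes, gene_sets, effect)
    genome_kb = cfg.n_chrom * cfg.chrom_len / 1000.0
    bg_total = cfg.background_rate * genome_kb
    lib_millions = cfg.library_size_mean / 1e6

    # gene properties shared by every sample: activity, width, signal mean
    widths = np.clip(
        np.round(rng.normal(cfg.peak_width_mean, 0.15 * cfg.peak_width_mean, n_genes)),
        2 * READ_LEN,
        None,
    ).astype(np.int64)
    active = {m: rng.random(n_genes) < cfg.active_prob for m in cfg.marks}
    sigma = cfg.signal_lognorm_sigma
    mu = np.log(cfg.signal_reads_per_peak) - sigma**2 / 2.0
    signal = {m: rng.lognormal(mu, sigma, n_genes) for m in cfg.marks}

    tss = np.array([g.tss for g in genes], dtype=np.int64)
    chrom_of = np.array([g.chrom for g in genes])
    peak_start = np.maximum(tss - widths // 2, 0)
    peak_end = peak_start + widths
    peaks_by_mark = {
        m: [
            GenomicInterval(str(chrom_of[i]), int(peak_start[i]), int(peak_end[i]))
            for i in np.flatnonzero(active[m])
        ]
        for m in cfg.marks
    }

    samples: list[SimSample] = []
    expected_score: dict[str, pd.DataFrame] = {}
    for m in cfg.marks:
        cols = {}
        for grp in cfg.groups:
            boost = np.where(
                target & (grp == effect.group) & (m == effect.assay),
                1.0 + effect.effect_size,
                1.0,
            )
            exp = np.where(
                active[m], signal[m] * boost / ((widths / 1000.0) * lib_millions), np.nan
            )
            cols[grp] = exp
        df = pd.DataFrame(cols, index=[g.gene_id for g in genes])
        df.index.name = "gene_id"
        expected_score[m] = df

    for grp in cfg.groups:
        for l in range(cfg.lines_per_group):
            line_id = f"{grp}{l + 1}"
            for r in range(cfg.replicates_per_line):
                input_reads = _background_reads(cfg, rng)
                for m in cfg.marks:
                    boost = np.where(
                        target & (grp == effect.group) & (m == effect.assay),
                        1.0 + effect.effect_size,
                        1.0,
                    )
                    lam = np.where(active[m], signal[m] * boost, 0.0)
                    counts = rng.poisson(lam)
                    sig_reads = _reads_in_peaks(
                        chrom_of, peak_start, peak_end, counts, rng
                    )
                    bg_reads = _background_reads(cfg, rng)
                    reads = pd.concat([sig_reads, bg_reads], ignore_index=True)
                    lib = max(int(rng.poisson(cfg.library_size_mean)), len(reads))
                    samples.append(
                        SimSample(
                            sample_id=f"{line_id}_rep{r + 1}_{m}",
                            group=grp,
                            line_id=line_id,
                            replicate=r + 1,
                            mark=m,
                            peaks=peaks_by_mark[m],
                            reads=reads,
                            library_size=lib,
                        )
                    )
                lib = max(int(rng.poisson(cfg.library_size_mean)), len(input_reads))
                samples.append(
                    SimSample(
                        sample_id=f"{line_id}_rep{r + 1}_input",
                        group=grp,
                        line_id=line_id,
                        replicate=r + 1,
                        mark="input",
                        peaks=[],
                        reads=input_reads,
                        library_size=lib,
                    )
                )

    truth = {
        "expected_score": expected_score,
        "signal": signal,
        "active": active,
        "widths": widths,
        "target_gene_mask": target,
        "expected_background_reads": bg_total,
    }
    return samples, truth


def _background_reads(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    frames = []
    per_chrom_kb = cfg.chrom_len / 1000.0
    for chrom in cfg.chrom_names:
        n = rng.poisson(cfg.background_rate * per_chrom_kb)
        starts = rng.integers(0, cfg.chrom_len - READ_LEN, size=n)
        frames.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + READ_LEN})
        )
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["chrom", "start"], kind="mergesort", ignore_index=True)


def _reads_in_peaks(chrom_of, peak_start, peak_end, counts, rng) -> pd.DataFrame:
    idx = np.repeat(np.arange(len(counts)), counts)
    lo = peak_start[idx]
    hi = peak_end[idx] - READ_LEN
    starts = lo + (rng.random(len(idx)) * (hi - lo)).astype(np.int64)
    df = pd.DataFrame(
        {"chrom": chrom_of[idx], "start": starts, "end": starts + READ_LEN}
    )
    return df.sort_values(["chrom", "start"], kind="mergesort", ignore_index=True)


# ---------------------------------------------------------------------------
# methylation channel


def generate_meth(
    cfg: SimConfig,
    genes: list[GeneAnnotation],
    gene_sets: list[GeneSet],
    rng: np.random.Generator,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Per-sample CpG methylation frequency tables.

    CpG sites follow a Poisson density along each chromosome. Each site
    carries a shared latent methylation level (logit-normal around the
    base mean, lowered inside the +/-1 kb TSS valley); each sample adds
    its own logit wobble and binomial sampling at Poisson coverage. The
    memory effect deepens the valley for target-set genes in one group.
    """
    cfg.validate()
    effect = cfg.memory_effect
    target = _target_gene_mask(genes, gene_sets, effect)

    chroms_all, pos_all = [], []
    for chrom in cfg.chrom_names:
        n = rng.poisson(cfg.cpg_density * cfg.chrom_len / 1000.0)
        pos = np.unique(rng.integers(0, cfg.chrom_len, size=n))
        chroms_all.append(np.full(len(pos), chrom))
        pos_all.append(pos)
    chroms = np.concatenate(chroms_all)
    pos = np.concatenate(pos_all)
    n_sites = len(pos)

    # per-(site, group) mean: valley within +/-1 kb of a TSS
    depth = {grp: np.zeros(n_sites) for grp in cfg.groups}
    gene_depth = {
        grp: np.where(
            target & (grp == effect.group) & (effect.assay == "meth"),
            np.clip(cfg.tss_valley_depth + effect.effect_size, 0.0, 1.0),
            cfg.tss_valley_depth,
        )
        for grp in cfg.groups
    }
    for gi, g in enumerate(genes):
        near = (chroms == g.chrom) & (np.abs(pos - g.tss) <= 1000)
        for grp in cfg.groups:
            depth[grp][near] = gene_depth[grp][gi]

    eps = 1e-3
    base = np.clip(cfg.meth_base_mean, eps, 1 - eps)
    u_site = rng.normal(0.0, cfg.meth_site_sigma, n_sites)

    samples: dict[str, pd.DataFrame] = {}
    for grp in cfg.groups:
        mean_grp = np.clip(base * (1.0 - depth[grp]), eps, 1 - eps)
        logit_grp = logit(mean_grp) + u_site
        for r in range(cfg.meth_replicates_per_group):
            p = expit(logit_grp + rng.normal(0.0, cfg.meth_sample_sigma, n_sites))
            coverage = rng.poisson(cfg.meth_coverage_mean, n_sites)
            meth_calls = rng.binomial(coverage, p)
            keep = coverage > 0
            df = pd.DataFrame(
                {
                    "chromosome": chroms[keep],
                    "start": pos[keep],
                    "end": pos[keep] + 1,
                    "num_motifs_in_group": 1,
                    "called_sites": coverage[keep],
                    "called_sites_methylated": meth_calls[keep],
                    "methylated_frequency": meth_calls[keep] / coverage[keep],
                    "group_sequence": "CG",
                }
            )
            samples[f"{grp}_animal{r + 1}"] = df

    truth = {
        "gene_depth": gene_depth,
        "target_gene_mask": target,
        "base_mean": base,
        "site_positions": pos,
        "site_chroms": chroms,
    }
    return samples, truth


def meth_replicate_pairs(cfg: SimConfig) -> list[tuple[str, str, str]]:
    """Replicate pairing consumed by center_and_average: two animals per
    group averaged into one per-group vector."""
    if cfg.meth_replicates_per_group != 2:
        raise ValueError("replicate averaging is defined for two animals per group")
    return [(f"{grp}_animal1", f"{grp}_animal2", grp) for grp in cfg.groups]


# ---------------------------------------------------------------------------
# qPCR channel


def generate_qpcr(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Ct table for the renal qPCR panel plus the calibrator group.

    The reference gene (beta-actin-like) Ct is ~N(18, sd); the target Ct
    adds a per-gene baseline dCt, minus log2(fold change) in the affected
    group, plus per-well noise. Fold changes not listed default to 1.
    """
    cfg.validate()
    unknown = set(cfg.qpcr_fold_changes) - set(cfg.qpcr_genes)
    if unknown:
        raise ValueError(f"qpcr_fold_changes references unknown genes: {sorted(unknown)}")
    affected = cfg.memory_effect.group
    rows = []
    base_dct_cal = 4.0  # calibrator expresses the panel strongly
    ipsc_shift = cfg.qpcr_ipsc_delta_ct  # iPSCs express it weakly by default
    rng_normal = rng.normal

    def emit(group, line_id, gene, dct_mean):
        ct_ref = rng_normal(18.0, 0.3)
        noise = rng_normal(0.0, cfg.qpcr_noise_sd) if cfg.qpcr_noise_sd > 0 else 0.0
        ct_tgt = ct_ref + dct_mean + noise
        rows.append(
            {
                "sample_id": f"{line_id}_w{len(rows)}",
                "group": group,
                "line_id": line_id,
                "gene": gene,
                "ct_target": ct_tgt,
                "ct_reference": ct_ref,
            }
        )

    for gene in cfg.qpcr_genes:
        fold = float(cfg.qpcr_fold_changes.get(gene, 1.0))
        for grp in cfg.groups:
            dct = base_dct_cal + ipsc_shift
            if grp == affected and fold != 1.0:
                dct -= np.log2(fold)
            for l in range(cfg.qpcr_lines_per_group):
                line_id = f"{grp}-L{l + 1}"
                for _w in range(cfg.qpcr_wells_per_line):
                    emit(grp, line_id, gene, dct)
        for _w in range(cfg.qpcr_wells_per_line):
            emit(cfg.qpcr_calibrator_group, f"{cfg.qpcr_calibrator_group}-L1", gene, base_dct_cal)
    return pd.DataFrame(rows)
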