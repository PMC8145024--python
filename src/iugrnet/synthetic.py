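"""Synthetic cohort, expression, sequence, gene-set and qPCR generation.

Emulates the study design every downstream stage expects: one sire mated to
eight dams, litters of 10-14 fetuses sampled at 63 dpc, a configurable
number of growth-restricted fetuses per litter (additive negative weight
shift), discordant sib-pair selection of 12 IUGR vs 12 AGA fetuses, and
log2 expression with dam (litter) random effects, sex effects, planted
group effects on a subset of probes, and negative miRNA-to-target coupling.
Transcript regions carry planted binding sites that are the exact reverse
complement of the paired mature miRNA, guaranteeing seed pairing and a
strongly negative duplex MFE.

Everything is reproducible: each generator stage draws from its own RNG
stream derived from ``SimConfig.seed``, so identical configs give
byte-identical outputs regardless of which stages a caller runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .hybridization import TranscriptRegion, transcribe
from .phenotype import AGA, IUGR, FetusRecord, classify_iugr, select_discordant_pairs
from .preprocessing import ExpressionMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimBundle",
    "simulate_cohort",
    "simulate_expression",
    "simulate_sequences",
    "simulate_gene_sets",
    "simulate_known_lists",
    "simulate_qpcr",
    "simulate_all",
    "annotation_from_truth",
]

_BASES_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASES_RNA = np.frombuffer(b"ACGU", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    # cohort
    n_dams: int = 8
    litter_size_range: tuple = (10, 14)
    n_restricted_per_litter: int = 2
    n_per_group: int = 12
    weight_mean: float = 175.0  # grams
    weight_sd: float = 8.0
    dam_weight_sd: float = 8.0
    growth_restriction_shift: float = 62.0  # matches the observed AGA-IUGR gap
    # probes / truth
    n_mirna_probes: int = 120
    n_mrna_probes: int = 1500
    n_true_de_mirna: int = 12
    n_true_de_mrna: int = 60
    mirna_up_fraction: float = 2.0 / 3.0
    mrna_up_fraction: float = 0.5
    n_planted_pairs: int = 24
    de_effect_size: float = 1.0  # log2 units
    coupling_strength: float = 1.5  # beta, log2 per centered log2
    # expression nuisance structure
    dam_sd: float = 0.3
    sex_effect: float = 0.2
    sex_effect_fraction: float = 0.1
    noise_sd: float = 0.2
    baseline_range: tuple = (6.0, 12.0)
    absent_probe_fraction: float = 0.05
    absent_sample_fraction: float = 0.4
    # sequences
    mirna_len_range: tuple = (20, 23)
    min_gc_mirna: int = 8
    n_long_mirna: int = 3  # probes annotated with >= 30 nt sequences
    utr3_len_range: tuple = (600, 2600)
    utr5_len_range: tuple = (150, 450)
    cds_len_range: tuple = (900, 3100)
    site_flank_len: int = 30
    # gene sets
    n_gene_sets: int = 20
    set_size_range: tuple = (10, 40)
    n_enriched_sets: int = 3
    enriched_set_truth_fraction: float = 0.7
    # qPCR
    n_qpcr_mirna: int = 4
    n_qpcr_mrna: int = 4
    qpcr_ct_noise: float = 0.05

    def validate(self) -> "SimConfig":
        if self.litter_size_range[0] < 4:
            raise ValueError(
                "litter_size_range lower bound must be >= 4 (the littermate "
                "2-SD rule is degenerate below that)"
            )
        if self.litter_size_range[0] > self.litter_size_range[1]:
            raise ValueError("litter_size_range must be (low, high)")
        for name in ("weight_sd", "dam_weight_sd", "dam_sd", "sex_effect", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.coupling_strength < 0:
            raise ValueError("coupling_strength must be >= 0")
        if self.n_true_de_mirna > self.n_mirna_probes - self.n_long_mirna:
            raise ValueError("too many true DE miRNAs for the probe count")
        if self.n_true_de_mrna > self.n_mrna_probes:
            raise ValueError("too many true DE mRNAs for the probe count")
        if self.n_planted_pairs > self.n_true_de_mirna * self.n_true_de_mrna:
            raise ValueError("n_planted_pairs exceeds n_true_de_mirna * n_true_de_mrna")
        if self.n_planted_pairs > self.n_true_de_mrna:
            raise ValueError(
                "planted pairs use distinct genes: n_planted_pairs must be "
                "<= n_true_de_mrna"
            )
        for rng_name in ("utr3_len_range", "utr5_len_range", "cds_len_range"):
            lo, hi = getattr(self, rng_name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{rng_name} must be >= 1 and ordered")
        if self.n_restricted_per_litter < 1:
            raise ValueError("need at least one restricted fetus per litter")
        return self


@dataclass
class SimTruth:
    """Planted ground truth; the yardstick for every downstream stage."""

    de_mirna: dict = field(default_factory=dict)  # probe_id -> "up"/"down"
    de_mrna: dict = field(default_factory=dict)  # probe_id -> "up"/"down"
    planted_pairs: list = field(default_factory=list)  # (mirna_probe, gene_id)
    planted_sites: list = field(default_factory=list)  # dicts: gene/region/offset
    enriched_set_ids: list = field(default_factory=list)
    restricted_fetus_ids: list = field(default_factory=list)
    mirna_sequences: dict = field(default_factory=dict)  # probe_id -> mature RNA
    gene_map: dict = field(default_factory=dict)  # mRNA probe_id -> gene symbol

    def gene_direction(self, gene_id: str) -> str:
        for probe, g in self.gene_map.items():
            if g == gene_id:
                return self.de_mrna.get(probe, "none")
        return "none"

    def validate(self) -> "SimTruth":
        gene_dirs = {self.gene_map[p]: d for p, d in self.de_mrna.items()}
        sites_by_gene = {}
        for s in self.planted_sites:
            sites_by_gene.setdefault((s["mirna_id"], s["gene_id"]), []).append(s)
        for mirna, gene in self.planted_pairs:
            if mirna not in self.de_mirna:
                raise AssertionError(f"planted pair miRNA {mirna} not in DE truth")
            if gene not in gene_dirs:
                raise AssertionError(f"planted pair gene {gene} not in DE truth")
            if self.de_mirna[mirna] == gene_dirs[gene]:
                raise AssertionError(
                    f"planted pair ({mirna}, {gene}) directions must be opposite"
                )
            if self.planted_sites and not sites_by_gene.get((mirna, gene)):
                raise AssertionError(f"planted pair ({mirna}, {gene}) has no site")
        return self

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        return cls(**json.loads(text))


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


def _random_seq(rng, n: int, alphabet=_BASES_DNA) -> str:
    return alphabet[rng.integers(0, 4, n)].tobytes().decode("ascii")


def _mature_mirna(rng, config: SimConfig) -> str:
    lo, hi = config.mirna_len_range
    n = int(rng.integers(lo, hi + 1))
    while True:
        seq = _random_seq(rng, n, _BASES_RNA)
        if seq.count("G") + seq.count("C") >= config.min_gc_mirna:
            return seq


def simulate_cohort(config: SimConfig):
    """Fetuses for every litter plus the full planted-truth plan.

    Returns ``(fetuses, truth)``.  The truth carries restricted fetus ids,
    the DE probe plan with signed directions, the planted (miRNA, gene)
    pairs, mature miRNA sequences, and the probe-to-gene map; sites are
    filled in by :func:`simulate_sequences`.
    """
    config.validate()
    rng = _rng(config, 0)

    fetuses, restricted = [], []
    for d in range(1, config.n_dams + 1):
        dam = f"D{d}"
        size = int(rng.integers(config.litter_size_range[0], config.litter_size_range[1] + 1))
        dam_mean = config.weight_mean + rng.normal(0.0, config.dam_weight_sd)
        sexes = rng.integers(0, 2, size)
        if sexes.min() == sexes.max():  # force both sexes into every litter
            sexes[-1] = 1 - sexes[-1]
        shifted = rng.choice(size, size=min(config.n_restricted_per_litter, size), replace=False)
        for k in range(size):
            fid = f"{dam}_F{k + 1:02d}"
            w = dam_mean + rng.normal(0.0, config.weight_sd)
            if k in shifted:
                w -= config.growth_restriction_shift
                restricted.append(fid)
            fetuses.append(
                FetusRecord(fid, dam, "male" if sexes[k] else "female", max(w, 1.0))
            )

    truth = SimTruth(restricted_fetus_ids=sorted(restricted))

    mirna_ids = [f"mir-{i + 1:03d}" for i in range(config.n_mirna_probes)]
    long_ids = set(mirna_ids[-config.n_long_mirna :]) if config.n_long_mirna else set()
    for mid in mirna_ids:
        if mid in long_ids:
            n = int(rng.integers(30, 41))
            truth.mirna_sequences[mid] = _random_seq(rng, n, _BASES_RNA)
        else:
            truth.mirna_sequences[mid] = _mature_mirna(rng, config)

    mrna_probes = [f"PR{i + 1:05d}" for i in range(config.n_mrna_probes)]
    truth.gene_map = {p: f"G{i + 1:05d}" for i, p in enumerate(mrna_probes)}

    eligible = [m for m in mirna_ids if m not in long_ids]
    de_mir = rng.choice(eligible, size=config.n_true_de_mirna, replace=False)
    n_up_mir = int(round(config.n_true_de_mirna * config.mirna_up_fraction))
    for i, mid in enumerate(sorted(de_mir)):
        truth.de_mirna[mid] = "up" if i < n_up_mir else "down"

    de_probe = rng.choice(mrna_probes, size=config.n_true_de_mrna, replace=False)
    n_up_gene = int(round(config.n_true_de_mrna * config.mrna_up_fraction))
    for i, probe in enumerate(sorted(de_probe)):
        truth.de_mrna[probe] = "up" if i < n_up_gene else "down"

    up_mirs = sorted(m for m, d in truth.de_mirna.items() if d == "up")
    down_mirs = sorted(m for m, d in truth.de_mirna.items() if d == "down")
    up_genes = sorted(truth.gene_map[p] for p, d in truth.de_mrna.items() if d == "up")
    down_genes = sorted(truth.gene_map[p] for p, d in truth.de_mrna.items() if d == "down")
    rng.shuffle(up_genes)
    rng.shuffle(down_genes)
    for i in range(config.n_planted_pairs):
        take_down = (i % 2 == 0 and down_genes and up_mirs) or not (up_genes and down_mirs)
        if take_down:
            if not (down_genes and up_mirs):
                raise ValueError("cannot honor n_planted_pairs with this direction split")
            gene = down_genes.pop()
            mirna = up_mirs[int(rng.integers(0, len(up_mirs)))]
        else:
            gene = up_genes.pop()
            mirna = down_mirs[int(rng.integers(0, len(down_mirs)))]
        truth.planted_pairs.append((mirna, gene))
    truth.planted_pairs.sort()
    return fetuses, truth.validate()


def annotation_from_truth(truth: SimTruth) -> pd.DataFrame:
    """Probe annotation table (class, gene symbol, mature sequence)."""
    rows = [
        {"probe_id": m, "probe_class": "miRNA", "gene_symbol": "", "mature_sequence": s}
        for m, s in truth.mirna_sequences.items()
    ]
    rows += [
        {"probe_id": p, "probe_class": "mRNA", "gene_symbol": g, "mature_sequence": ""}
        for p, g in truth.gene_map.items()
    ]
    return pd.DataFrame(rows)


def simulate_expression(config: SimConfig, fetuses, truth: SimTruth):
    """Log2 expression matrices for the selected cohort.

    value = baseline + signed group effect (truth probes only) + sex effect
    + shared dam effect + Gaussian noise; planted-pair mRNAs additionally
    subtract ``coupling_strength x centered paired miRNA value``.  Returns
    ``(mirna_matrix, mrna_matrix)`` with present-call masks in which a
    configurable fraction of (non-truth) probes is forced absent in more
    than 20% of samples.
    """
    rng = _rng(config, 1)
    fetuses = list(fetuses)
    ids = [f.fetus_id for f in fetuses]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate fetus ids in cohort")
    for f in fetuses:
        if f.group not in (IUGR, AGA):
            raise ValueError(f"fetus {f.fetus_id} has no group label")
    n = len(fetuses)
    group = np.array([1.0 if f.group == IUGR else 0.0 for f in fetuses])
    male = np.array([1.0 if f.sex == "male" else 0.0 for f in fetuses])
    dams = sorted({f.dam for f in fetuses})
    dam_idx = np.array([dams.index(f.dam) for f in fetuses])

    def build(probe_ids, de_truth):
        m = len(probe_ids)
        baseline = rng.uniform(*config.baseline_range, m)
        sex_sign = np.where(
            rng.random(m) < config.sex_effect_fraction,
            rng.choice([-1.0, 1.0], m),
            0.0,
        )
        dam_eff = rng.normal(0.0, config.dam_sd, (m, len(dams)))
        noise = rng.normal(0.0, config.noise_sd, (m, n))
        de = np.zeros(m)
        for k, p in enumerate(probe_ids):
            d = de_truth.get(p)
            if d:
                de[k] = config.de_effect_size if d == "up" else -config.de_effect_size
        vals = (
            baseline[:, None]
            + de[:, None] * group[None, :]
            + (config.sex_effect * sex_sign)[:, None] * male[None, :]
            + dam_eff[:, dam_idx]
            + noise
        )
        return pd.DataFrame(vals, index=probe_ids, columns=ids)

    mirna_vals = build(list(truth.mirna_sequences), truth.de_mirna)
    mrna_vals = build(list(truth.gene_map), truth.de_mrna)

    gene_to_probe = {g: p for p, g in truth.gene_map.items()}
    for mirna, gene in truth.planted_pairs:
        x = mirna_vals.loc[mirna].to_numpy()
        probe = gene_to_probe[gene]
        mrna_vals.loc[probe] = mrna_vals.loc[probe].to_numpy() - config.coupling_strength * (
            x - x.mean()
        )

    def mask(probe_ids, de_truth):
        m = pd.DataFrame(True, index=probe_ids, columns=ids)
        non_truth = [p for p in probe_ids if p not in de_truth]
        k = int(round(config.absent_probe_fraction * len(probe_ids)))
        k = min(k, len(non_truth))
        if k:
            absent = rng.choice(non_truth, size=k, replace=False)
            n_absent = max(int(np.ceil(config.absent_sample_fraction * n)), int(0.2 * n) + 1)
            for p in absent:
                cols = rng.choice(n, size=n_absent, replace=False)
                m.iloc[m.index.get_loc(p), cols] = False
        return m

    mirna_em = ExpressionMatrix(mirna_vals, mask(list(truth.mirna_sequences), truth.de_mirna))
    mrna_em = ExpressionMatrix(mrna_vals, mask(list(truth.gene_map), truth.de_mrna))
    return mirna_em, mrna_em


def simulate_sequences(config: SimConfig, truth: SimTruth, mirna_sequences=None):
    """Transcript regions (DNA on disk convention) with planted binding sites.

    Every gene receives 3UTR/5UTR/CDS records with lengths spanning the
    fragmentation threshold; each planted pair embeds, in the gene's 3'UTR,
    the DNA reverse complement of the full mature miRNA at a recorded
    offset.  Returns ``{gene_id: [TranscriptRegion, ...]}`` and appends to
    ``truth.planted_sites``.
    """
    rng = _rng(config, 2)
    if mirna_sequences is None:
        mirna_sequences = truth.mirna_sequences
    comp = {"A": "T", "C": "G", "G": "C", "U": "A"}
    regions: dict[str, list[TranscriptRegion]] = {}
    ranges = {
        "3UTR": config.utr3_len_range,
        "5UTR": config.utr5_len_range,
        "CDS": config.cds_len_range,
    }
    sites_by_gene: dict[str, list] = {}
    for mirna, gene in truth.planted_pairs:
        sites_by_gene.setdefault(gene, []).append(mirna)

    truth.planted_sites = []  # regenerated below; keeps reruns idempotent
    for gene in sorted(set(truth.gene_map.values())):
        recs = []
        for region in ("3UTR", "5UTR", "CDS"):
            lo, hi = ranges[region]
            seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
            if region == "3UTR":
                for mirna in sites_by_gene.get(gene, []):
                    site = "".join(comp[b] for b in reversed(mirna_sequences[mirna]))
                    if len(site) > len(seq):
                        raise ValueError(
                            f"planted site ({len(site)} nt) longer than host "
                            f"region {gene}/3UTR ({len(seq)} nt)"
                        )
                    lo_off = min(config.site_flank_len, len(seq) - len(site))
                    hi_off = max(len(seq) - len(site) - config.site_flank_len, lo_off)
                    off = int(rng.integers(lo_off, hi_off + 1))
                    seq = seq[:off] + site + seq[off + len(site) :]
                    truth.planted_sites.append(
                        {
                            "mirna_id": mirna,
                            "gene_id": gene,
                            "region": region,
                            "offset": off,
                            "length": len(site),
                        }
                    )
            recs.append(TranscriptRegion(gene, region, seq))
        regions[gene] = recs
    truth.validate()
    return regions


def simulate_gene_sets(config: SimConfig, truth: SimTruth):
    """GMT-style gene sets; a few are enriched for planted target genes."""
    rng = _rng(config, 3)
    universe = sorted(set(truth.gene_map.values()))
    planted_genes = sorted({g for _, g in truth.planted_pairs})
    others = [g for g in universe if g not in set(planted_genes)]
    sets = {}
    truth.enriched_set_ids = []
    for k in range(config.n_gene_sets):
        set_id = f"SET{k + 1:03d}"
        size = int(rng.integers(config.set_size_range[0], config.set_size_range[1] + 1))
        if k < config.n_enriched_sets:
            n_truth = min(
                int(round(config.enriched_set_truth_fraction * size)), len(planted_genes)
            )
            members = list(rng.choice(planted_genes, size=n_truth, replace=False))
            members += list(rng.choice(others, size=size - n_truth, replace=False))
            truth.enriched_set_ids.append(set_id)
            name = f"planted_process_{k + 1}"
        else:
            members = list(rng.choice(universe, size=size, replace=False))
            name = f"random_process_{k + 1}"
        sets[set_id] = (name, sorted(set(members)))
    return sets


def simulate_known_lists(config: SimConfig, truth: SimTruth):
    """Known-association miRNA lists (IUGR, muscle) leaving some DE miRNAs novel."""
    rng = _rng(config, 4)
    up = sorted(m for m, d in truth.de_mirna.items() if d == "up")
    non_de = sorted(set(truth.mirna_sequences) - set(truth.de_mirna))
    third = max(len(up) // 3, 1)
    known_iugr = set(up[:third]) | set(rng.choice(non_de, size=min(10, len(non_de)), replace=False))
    known_muscle = set(up[third : 2 * third]) | set(
        rng.choice(non_de, size=min(10, len(non_de)), replace=False)
    )
    return sorted(known_iugr), sorted(known_muscle)


def simulate_qpcr(config: SimConfig, truth: SimTruth, mirna_em, mrna_em):
    """Fluidigm-style Ct table derived from the simulated expression truth.

    Target Ct = 30 - log2 expression (+ small noise); housekeeping (ACTB,
    GAPDH) and the spike-in are near-constant.  Returns ``(ct_table,
    assay_map)`` where assay_map links assay ids to array probes.
    """
    rng = _rng(config, 5)
    up_m = sorted(m for m, d in truth.de_mirna.items() if d == "up")
    down_m = sorted(m for m, d in truth.de_mirna.items() if d == "down")
    mirna_assays = (up_m + down_m)[: config.n_qpcr_mirna]
    up_g = sorted(p for p, d in truth.de_mrna.items() if d == "up")
    down_g = sorted(p for p, d in truth.de_mrna.items() if d == "down")
    mrna_assays = [v for pair in zip(down_g, up_g) for v in pair][: config.n_qpcr_mrna]

    rows = []
    samples = list(mirna_em.sample_ids)

    def add(sample, assay, ct, cls):
        rows.append(
            {"sample_id": sample, "assay_id": assay, "ct": float(ct), "assay_class": cls}
        )

    for s in samples:
        for probe in mirna_assays:
            ct = 30.0 - mirna_em.values.at[probe, s] + rng.normal(0, config.qpcr_ct_noise)
            add(s, f"q_{probe}", ct, "target_miRNA")
        for probe in mrna_assays:
            ct = 30.0 - mrna_em.values.at[probe, s] + rng.normal(0, config.qpcr_ct_noise)
            add(s, f"q_{probe}", ct, "target_mRNA")
        add(s, "ACTB", 18.0 + rng.normal(0, config.qpcr_ct_noise), "housekeeping")
        add(s, "GAPDH", 19.0 + rng.normal(0, config.qpcr_ct_noise), "housekeeping")
        add(s, "cel-miR-39-3p", 15.0 + rng.normal(0, config.qpcr_ct_noise), "spike_in")

    ct = pd.DataFrame(rows)
    assay_map = pd.DataFrame(
        [{"assay_id": f"q_{p}", "probe_id": p, "track": "miRNA"} for p in mirna_assays]
        + [{"assay_id": f"q_{p}", "probe_id": p, "track": "mRNA"} for p in mrna_assays]
    )
    return ct, assay_map


@dataclass
class SimBundle:
    """Everything one synthetic study produces, ready for the pipeline."""

    config: SimConfig
    truth: SimTruth
    fetuses: list
    cohort: list  # selected, labeled fetuses (2 x n_per_group)
    annotation: pd.DataFrame
    mirna: ExpressionMatrix
    mrna: ExpressionMatrix
    gene_regions: dict
    gene_sets: dict
    known_iugr: list
    known_muscle: list
    ct_table: pd.DataFrame
    assay_map: pd.DataFrame


def simulate_all(config: SimConfig) -> SimBundle:
    """Run every generator stage in study order and return the bundle."""
    fetuses, truth = simulate_cohort(config)
    labeled = classify_iugr(fetuses)
    cohort, _pairs = select_discordant_pairs(labeled, n_per_group=config.n_per_group)
    mirna_em, mrna_em = simulate_expression(config, cohort, truth)
    gene_regions = simulate_sequences(config, truth)
    gene_sets = simulate_gene_sets(config, truth)
    known_iugr, known_muscle = simulate_known_lists(config, truth)
    ct, assay_map = simulate_qpcr(config, truth, mirna_em, mrna_em)
    return SimBundle(
        config=config,
        truth=truth,
        fetuses=fetuses,
        cohort=cohort,
        annotation=annotation_from_truth(truth),
        mirna=mirna_em,
        mrna=mrna_em,
        gene_regions=gene_regions,
        gene_sets=gene_sets,
        known_iugr=known_iugr,
        known_muscle=known_muscle,
        ct_table=ct,
        assay_map=assay_map,
    )
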