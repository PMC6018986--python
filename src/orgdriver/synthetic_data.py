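"""Synthetic cell-type-enriched organoid study with planted ground truth.

Generates the full complement of inputs the downstream pipeline consumes:

* a proteome (spike-in-anchored iBAQ-like intensities, unfractionated and
  fractionated) and a transcriptome (ERCC-anchored negative-binomial counts)
  for three media conditions ("CV" stem-cell-enriched, "ENR" reference,
  "EN" enterocyte-enriched) in triplicate;
* a small genome with non-overlapping peaks tiled into TADs, a motif
  database with one causal "driver" PWM planted in a fraction of peaks,
  peak-level counts whose condition fold changes follow the planted motif,
  and a TF protein-expression table in which the driver TF is strongly
  differential.

Every planted quantity is recorded in a :class:`GroundTruth` so recovery can
be scored exactly. All randomness flows from a single integer seed; identical
seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as odio
from .motif_driver_selection import PWM

BASES = np.frombuffer(b"ACGT", dtype="S1")

# Detection-limit censoring: miss probability 0.9 far below the threshold,
# 0.05 far above, logistic in log10 intensity.
MISS_P_LOW = 0.05
MISS_P_HIGH = 0.90
MISS_WIDTH = 0.3  # logistic width, log10 units


@dataclass(frozen=True)
class SampleDesign:
    """Study layout: ordered condition labels x replicates."""

    conditions: tuple[str, ...] = ("CV", "ENR", "EN")
    replicates_per_condition: int = 3
    seed: int = 0

    def __post_init__(self):
        if len(self.conditions) < 2:
            raise ValueError("need at least 2 conditions")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if self.replicates_per_condition < 2:
            raise ValueError("need at least 2 replicates per condition")

    @property
    def samples(self) -> list[str]:
        return [
            f"{c}_{r + 1}"
            for c in self.conditions
            for r in range(self.replicates_per_condition)
        ]

    def samples_of(self, condition: str) -> list[str]:
        if condition not in self.conditions:
            raise KeyError(f"unknown condition {condition!r}")
        return [f"{condition}_{r + 1}" for r in range(self.replicates_per_condition)]

    def condition_of(self, sample: str) -> str:
        cond = sample.rsplit("_", 1)[0]
        if cond not in self.conditions:
            raise KeyError(f"sample {sample!r} does not match the design")
        return cond


@dataclass(frozen=True)
class SpikeInPanel:
    """Spike-in standards: feature id -> known input amount (amol-like units)."""

    entries: tuple[tuple[str, float], ...]

    def __post_init__(self):
        amounts = np.array([a for _, a in self.entries], dtype=float)
        if (amounts <= 0).any():
            raise ValueError("spike-in amounts must be strictly positive")
        if len({i for i, _ in self.entries}) != len(self.entries):
            raise ValueError("spike-in ids must be unique")
        if len(np.unique(amounts)) < 8:
            raise ValueError("panel needs at least 8 distinct amount levels")
        span = np.log10(amounts.max() / amounts.min())
        if span < 4:
            raise ValueError("panel must span at least 4 orders of magnitude")

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.entries]

    @property
    def amounts(self) -> pd.Series:
        return pd.Series({i: a for i, a in self.entries}, name="amount")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["id", "amount"])


def protein_spikein_panel(n_levels: int = 8, per_level: int = 6, lo: float = 10 ** 1.5, hi: float = 10 ** 6) -> SpikeInPanel:
    """UPS2-style panel: log-spaced amount levels, several proteins per level.

    The default range straddles the simulated proteome's copy-number
    distribution, as the real standard does on the iBAQ scale, so that a
    detection limit censors only the lowest levels."""
    levels = np.logspace(math.log10(lo), math.log10(hi), n_levels)
    entries = tuple(
        (f"UPS_{li + 1:02d}_{pi + 1}", float(levels[li]))
        for li in range(n_levels)
        for pi in range(per_level)
    )
    return SpikeInPanel(entries)


def ercc_spikein_panel(n: int = 92, lo: float = 0.5, hi: float = 5e4) -> SpikeInPanel:
    """ERCC-style panel: log-spaced RNA input amounts."""
    amounts = np.logspace(math.log10(lo), math.log10(hi), n)
    entries = tuple((f"ERCC-{i + 1:05d}", float(amounts[i])) for i in range(n))
    return SpikeInPanel(entries)


@dataclass(frozen=True)
class SyntheticGenome:
    chromosomes: dict[str, str]

    def __post_init__(self):
        if not self.chromosomes:
            raise ValueError("genome needs at least one chromosome")
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name} is empty")

    @property
    def sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}


def make_genome(n_chrom: int = 4, chrom_length: int = 500_000, seed: int = 0) -> SyntheticGenome:
    rng = np.random.default_rng(seed)
    chroms = {
        f"chr{i + 1}": rng.choice(BASES, size=chrom_length).tobytes().decode()
        for i in range(n_chrom)
    }
    return SyntheticGenome(chroms)


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed the way the outputs are keyed."""

    true_protein_copies: pd.DataFrame | None = None  # feature x condition
    true_mrna_copies: pd.DataFrame | None = None
    ratio_shift_genes: pd.DataFrame | None = None  # feature, log2_shift (per non-EN arm)
    de_genes: pd.DataFrame | None = None  # feature, log2fc in EN
    driver_motif_id: str | None = None
    driver_peaks: list[str] = field(default_factory=list)
    coordinated_tads: pd.DataFrame | None = None  # tad, sign
    differential_tfs: pd.DataFrame | None = None  # tf, log2fc in EN
    promoter_motif_genes: list[str] = field(default_factory=list)
    up_genes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {}
        for key, val in self.__dict__.items():
            if isinstance(val, pd.DataFrame):
                payload[key] = val.reset_index().to_dict(orient="list")
            else:
                payload[key] = val
        odio.write_json(payload, path)


@dataclass
class ExpressionStudy:
    """Proteome + transcriptome matrices with spike-ins and ground truth."""

    design: SampleDesign
    protein_unfractionated: pd.DataFrame  # features + spike-ins, iBAQ-like
    protein_fractionated: pd.DataFrame  # features only, deeper gain
    counts: pd.DataFrame  # features + ERCC rows, integer-valued
    protein_panel: SpikeInPanel
    ercc_panel: SpikeInPanel
    truth: GroundTruth


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _censor(intens: np.ndarray, missing_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Intensity-dependent missingness: logistic in log10 intensity around the
    missing_rate quantile, P(miss) from 0.05 well above to 0.9 well below."""
    if missing_rate == 0:
        return intens
    log_i = np.log10(intens)
    thresh = np.quantile(log_i, missing_rate)
    p_miss = MISS_P_LOW + (MISS_P_HIGH - MISS_P_LOW) / (1.0 + np.exp((log_i - thresh) / MISS_WIDTH))
    out = intens.copy()
    out[rng.random(intens.shape) < p_miss] = np.nan
    return out


def simulate_expression(
    design: SampleDesign,
    n_features: int = 2000,
    spike_panel: SpikeInPanel | None = None,
    ercc_panel: SpikeInPanel | None = None,
    noise_cv: float = 0.2,
    missing_rate: float = 0.1,
    gain_unfractionated: float = 100.0,
    gain_fractionated: float = 20.0,
    frac_de: float = 0.2,
    de_log2fc: float = 2.0,
    frac_ratio_shift: float = 0.05,
    ratio_shift_fold: float = 8.0,
    mrna_capture: float = 20.0,
    nb_dispersion: float = 20.0,
) -> ExpressionStudy:
    """Simulate matched proteome and transcriptome for the study design.

    Protein intensity = gain x true copies x lognormal(sigma(noise_cv)); the
    spike-ins obey the same per-matrix gain, anchoring the absolute scale.
    mRNA counts are negative-binomial around capture x true mRNA copies, with
    ERCC rows anchored the same way. A ``frac_de`` subset of genes changes in
    the last ("EN"-like) condition at both layers; a ``frac_ratio_shift``
    subset additionally shifts its protein/mRNA ratio by ``ratio_shift_fold``
    in every non-EN condition (same direction in all arms). With
    ``noise_cv=0`` and ``missing_rate=0`` the outputs are the exact planted
    values (counts become exact means, not draws).
    """
    if n_features < 100:
        raise ValueError("n_features must be >= 100")
    if not (0 <= missing_rate < 0.5):
        raise ValueError("missing_rate must be in [0, 0.5)")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    spike_panel = spike_panel or protein_spikein_panel()
    ercc_panel = ercc_panel or ercc_spikein_panel()
    rng = np.random.default_rng(design.seed)
    conds = list(design.conditions)
    en = conds[-1]
    samples = design.samples
    features = [f"gene{i + 1:05d}" for i in range(n_features)]

    base_protein = 10 ** rng.normal(4.0, 1.0, n_features)  # copies per cell
    ratio0 = 10 ** rng.normal(2.5, 0.5, n_features)  # protein copies per mRNA
    base_mrna = base_protein / ratio0

    n_de = int(round(frac_de * n_features))
    de_idx = rng.choice(n_features, size=n_de, replace=False)
    de_sign = rng.choice([-1.0, 1.0], size=n_de)
    de_lfc = de_sign * de_log2fc

    pool = np.setdiff1d(np.arange(n_features), de_idx)
    n_shift = int(round(frac_ratio_shift * n_features))
    shift_idx = rng.choice(pool, size=n_shift, replace=False)
    shift_sign = rng.choice([-1.0, 1.0], size=n_shift)
    shift_log2 = shift_sign * math.log2(ratio_shift_fold)

    # condition-level true copies
    prot = {c: base_protein.copy() for c in conds}
    mrna = {c: base_mrna.copy() for c in conds}
    for c in conds:
        if c == en:
            prot[c][de_idx] *= 2.0 ** de_lfc
            mrna[c][de_idx] *= 2.0 ** de_lfc
        else:
            # ratio shift: protein moves, mRNA stays -> protein/mRNA ratio shifts
            prot[c][shift_idx] *= 2.0 ** shift_log2
    true_prot = pd.DataFrame({c: prot[c] for c in conds}, index=features)
    true_mrna = pd.DataFrame({c: mrna[c] for c in conds}, index=features)

    sigma = _lognormal_sigma(noise_cv)

    def intensity_matrix(gain: float) -> pd.DataFrame:
        cols = {}
        for s in samples:
            c = design.condition_of(s)
            mu = np.concatenate([true_prot[c].to_numpy(), spike_panel.amounts.to_numpy()])
            noise = np.exp(rng.normal(0.0, sigma, mu.size)) if sigma > 0 else 1.0
            cols[s] = gain * mu * noise
        idx = features + spike_panel.ids
        return pd.DataFrame(cols, index=idx)

    prot_unfrac = intensity_matrix(gain_unfractionated)
    prot_frac_full = intensity_matrix(gain_fractionated)
    prot_frac = prot_frac_full.loc[features]  # spikes only in the unfractionated run

    if missing_rate > 0:
        prot_unfrac = pd.DataFrame(
            _censor(prot_unfrac.to_numpy(), missing_rate, rng),
            index=prot_unfrac.index, columns=prot_unfrac.columns,
        )
        prot_frac = pd.DataFrame(
            _censor(prot_frac.to_numpy(), missing_rate, rng),
            index=prot_frac.index, columns=prot_frac.columns,
        )

    count_cols = {}
    for s in samples:
        c = design.condition_of(s)
        mu = mrna_capture * np.concatenate([true_mrna[c].to_numpy(), ercc_panel.amounts.to_numpy()])
        if noise_cv > 0:
            p = nb_dispersion / (nb_dispersion + mu)
            count_cols[s] = rng.negative_binomial(nb_dispersion, p).astype(float)
        else:
            count_cols[s] = mu
    counts = pd.DataFrame(count_cols, index=features + ercc_panel.ids)

    truth = GroundTruth(
        true_protein_copies=true_prot,
        true_mrna_copies=true_mrna,
        ratio_shift_genes=pd.DataFrame(
            {"log2_shift": shift_log2}, index=[features[i] for i in shift_idx]
        ),
        de_genes=pd.DataFrame({"log2fc_en": de_lfc}, index=[features[i] for i in de_idx]),
        up_genes=[features[i] for i, s in zip(de_idx, de_sign) if s > 0],
    )
    return ExpressionStudy(
        design=design,
        protein_unfractionated=prot_unfrac,
        protein_fractionated=prot_frac,
        counts=counts,
        protein_panel=spike_panel,
        ercc_panel=ercc_panel,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# regulatory landscape
# ---------------------------------------------------------------------------


@dataclass
class RegulatoryLandscape:
    design: SampleDesign
    genome: SyntheticGenome
    peaks: pd.DataFrame  # chrom, start, end, name
    counts: pd.DataFrame  # peaks x samples
    motifs: list[PWM]
    tads: pd.DataFrame  # chrom, start, end, name
    genes: pd.DataFrame  # chrom, tss, strand, indexed by gene id
    tf_expression: pd.DataFrame  # TF x samples intensities
    tf_map: pd.DataFrame  # columns motif, tf
    truth: GroundTruth


def _random_pwm(length: int, rng: np.random.Generator, info: float = 0.85) -> np.ndarray:
    consensus = rng.integers(0, 4, length)
    mat = np.full((length, 4), (1.0 - info) / 3.0)
    mat[np.arange(length), consensus] = info
    return mat


def _sample_site(matrix: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cum = matrix.cumsum(axis=1)
    return (cum < rng.random(matrix.shape[0])[:, None]).sum(axis=1)


_COMP = np.array([3, 2, 1, 0])


def _embed(chrom_seqs: dict[str, bytearray], chrom: str, pos: int, site: np.ndarray,
           rng: np.random.Generator) -> None:
    if rng.random() < 0.5:
        site = _COMP[site[::-1]]
    seq = b"ACGT"
    for k, b in enumerate(site):
        chrom_seqs[chrom][pos + k] = seq[b]


def simulate_regulatory_landscape(
    design: SampleDesign,
    genome: SyntheticGenome | None = None,
    n_peaks: int = 2000,
    n_motifs: int = 50,
    n_tads: int = 200,
    driver_effect: float = 2.0,
    frac_driver_peaks: float = 0.3,
    frac_coordinated_tads: float = 0.05,
    coordinated_effect: float = 1.0,
    coordination: float = 0.95,
    peak_width: int = 400,
    decoy_embed_frac: float = 0.3,
    frac_differential_tfs: float = 0.4,
    driver_tf_log2fc: float = 2.0,
    n_genes: int = 400,
    frac_promoter_motif: float = 0.6,
    baseline_mean: float = 100.0,
    nb_dispersion: float = 10.0,
    tf_noise_cv: float = 0.2,
    seed: int | None = None,
) -> RegulatoryLandscape:
    """Simulate peaks, TADs, motifs, peak counts and TF expression.

    One driver PWM is embedded in ``frac_driver_peaks`` of the peaks; those
    peaks get a ``driver_effect`` log2-unit negative-binomial mean shift in
    the last ("EN"-like) condition. Decoy PWMs are embedded in random peaks
    independent of any fold change. ``frac_coordinated_tads`` of the TADs
    impose a shared fold-change sign (``coordination`` of member peaks) of
    ``coordinated_effect`` log2 units. The driver's TF is planted in the TF
    expression table at ``driver_tf_log2fc`` (>= 2, i.e. >= 4-fold).
    """
    if n_motifs < 2:
        raise ValueError("need at least 2 motifs (1 driver + >=1 decoy)")
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    genome = genome or make_genome(seed=int(rng.integers(2**31)))

    chrom_names = list(genome.chromosomes)
    sizes = genome.sizes
    # TADs tile the chromosomes without overlap
    per_chrom = np.full(len(chrom_names), n_tads // len(chrom_names))
    per_chrom[: n_tads % len(chrom_names)] += 1
    tad_rows, peak_rows = [], []
    ppt_base, ppt_extra = divmod(n_peaks, n_tads)
    tad_i = 0
    for ci, chrom in enumerate(chrom_names):
        n_t = int(per_chrom[ci])
        if n_t == 0:
            continue
        tad_len = sizes[chrom] // n_t
        for t in range(n_t):
            t_start = t * tad_len
            t_end = t_start + tad_len
            ppt = ppt_base + (1 if tad_i < ppt_extra else 0)
            spacing = tad_len // max(ppt, 1)
            if ppt and spacing <= peak_width:
                raise ValueError(
                    "TAD/peak geometry conflict: peaks would overlap "
                    f"(spacing {spacing} <= width {peak_width})"
                )
            name = f"tad{tad_i + 1:04d}"
            tad_rows.append((chrom, t_start, t_end, name))
            for p in range(ppt):
                p_start = t_start + p * spacing + (spacing - peak_width) // 2
                peak_rows.append((chrom, p_start, p_start + peak_width, name))
            tad_i += 1
    tads = pd.DataFrame(tad_rows, columns=["chrom", "start", "end", "name"])
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "tad"])
    peaks.insert(3, "name", [f"peak{i + 1:05d}" for i in range(len(peaks))])
    n_peaks = len(peaks)

    # motif database: motif 0 is the driver
    lengths = rng.integers(8, 13, n_motifs)
    motifs = [PWM(id=f"motif{m + 1:03d}", matrix=_random_pwm(int(lengths[m]), rng)) for m in range(n_motifs)]
    driver = motifs[0]

    chrom_seqs = {c: bytearray(s, "ascii") for c, s in genome.chromosomes.items()}
    n_driver = int(round(frac_driver_peaks * n_peaks))
    driver_idx = np.sort(rng.choice(n_peaks, size=n_driver, replace=False))

    # embedded instances never overlap within a peak, so planting a decoy
    # cannot destroy the driver's site (or another decoy's)
    occupied: dict[int, list[tuple[int, int]]] = {}

    def _place(peak_i: int, pwm: PWM) -> int | None:
        taken = occupied.setdefault(peak_i, [])
        for _ in range(20):
            off = int(rng.integers(0, peak_width - pwm.length + 1))
            if all(off + pwm.length <= s or off >= e for s, e in taken):
                taken.append((off, off + pwm.length))
                return off
        return None

    for i in driver_idx:
        row = peaks.iloc[int(i)]
        off = _place(int(i), driver)
        if off is not None:
            _embed(chrom_seqs, row.chrom, int(row.start) + off, _sample_site(driver.matrix, rng), rng)
    for m in motifs[1:]:
        n_emb = int(round(decoy_embed_frac * n_peaks))
        for i in rng.choice(n_peaks, size=n_emb, replace=False):
            row = peaks.iloc[int(i)]
            off = _place(int(i), m)
            if off is not None:
                _embed(chrom_seqs, row.chrom, int(row.start) + off, _sample_site(m.matrix, rng), rng)

    # genes: TSSs on a grid away from nothing in particular; a subset of "up"
    # genes carries the driver motif in its promoter window
    gene_rows = []
    for gi in range(n_genes):
        chrom = chrom_names[gi % len(chrom_names)]
        tss = int(rng.integers(500, sizes[chrom] - 500))
        gene_rows.append((f"g{gi + 1:04d}", chrom, tss, "+" if rng.random() < 0.5 else "-"))
    genes = pd.DataFrame(gene_rows, columns=["gene", "chrom", "tss", "strand"]).set_index("gene")
    n_up = max(1, n_genes // 4)
    up_genes = list(genes.index[rng.choice(n_genes, size=n_up, replace=False)])
    n_planted = int(round(frac_promoter_motif * n_up))
    promoter_motif_genes = list(rng.choice(up_genes, size=n_planted, replace=False))
    # promoter instances are planted as consensus sites so a strict
    # best-match threshold (consensus minus a margin) can recover them
    consensus_site = driver.matrix.argmax(axis=1)
    for g in promoter_motif_genes:
        row = genes.loc[g]
        pos = int(row.tss) - 250 + int(rng.integers(0, 500 - driver.length + 1))
        pos = min(max(pos, 0), sizes[row.chrom] - driver.length)
        _embed(chrom_seqs, row.chrom, pos, consensus_site, rng)

    genome = SyntheticGenome({c: bytes(b).decode() for c, b in chrom_seqs.items()})

    # coordinated TADs: shared fold-change sign on `coordination` of members
    n_coord = int(np.ceil(frac_coordinated_tads * n_tads))
    coord_tads = list(tads["name"].iloc[np.sort(rng.choice(len(tads), size=n_coord, replace=False))])
    coord_sign = {t: float(rng.choice([-1.0, 1.0])) for t in coord_tads}

    # per-peak condition log2 effects in the EN-like condition
    conds = list(design.conditions)
    en = conds[-1]
    effect = np.zeros(n_peaks)
    effect[driver_idx] += driver_effect
    is_driver = np.zeros(n_peaks, dtype=bool)
    is_driver[driver_idx] = True
    for t in coord_tads:
        members = np.flatnonzero((peaks["tad"] == t).to_numpy() & ~is_driver)
        if members.size == 0:
            continue
        signs = np.full(members.size, coord_sign[t])
        n_flip = int(round((1.0 - coordination) * members.size))
        if n_flip:
            signs[rng.choice(members.size, size=n_flip, replace=False)] *= -1.0
        effect[members] += signs * coordinated_effect

    base = baseline_mean * 2.0 ** rng.normal(0.0, 1.0, n_peaks)
    size_factors = {s: float(2.0 ** rng.normal(0.0, 0.15)) for s in design.samples}
    count_cols = {}
    for s in design.samples:
        mu = base * (2.0 ** effect if design.condition_of(s) == en else 1.0)
        mu = np.maximum(mu * size_factors[s], 1e-8)
        p = nb_dispersion / (nb_dispersion + mu)
        count_cols[s] = rng.negative_binomial(nb_dispersion, p).astype(float)
    counts = pd.DataFrame(count_cols, index=peaks["name"].to_numpy())

    # TF expression: one TF per motif, ~10% of motifs get a second linked TF
    tf_ids = [f"TF{m + 1:03d}" for m in range(n_motifs)]
    map_rows = [(motifs[m].id, tf_ids[m]) for m in range(n_motifs)]
    extra = rng.choice(np.arange(1, n_motifs), size=max(1, n_motifs // 10), replace=False)
    for m in extra:
        map_rows.append((motifs[int(m)].id, f"TF{int(m) + 1:03d}b"))
    tf_map = pd.DataFrame(map_rows, columns=["motif", "tf"])
    all_tfs = sorted(tf_map["tf"].unique())

    n_diff = max(1, int(round(frac_differential_tfs * len(all_tfs))))
    diff_pool = [t for t in all_tfs if t != tf_ids[0]]
    diff_tfs = [tf_ids[0]] + list(rng.choice(diff_pool, size=n_diff - 1, replace=False))
    tf_lfc = {t: 0.0 for t in all_tfs}
    for t in diff_tfs:
        tf_lfc[t] = driver_tf_log2fc if t == tf_ids[0] else float(rng.choice([-1.0, 1.0]) * rng.uniform(1.5, 2.5))
    sigma = _lognormal_sigma(tf_noise_cv)
    tf_base = 10 ** rng.normal(5.0, 0.5, len(all_tfs))
    tf_cols = {}
    for s in design.samples:
        fac = np.array([2.0 ** tf_lfc[t] if design.condition_of(s) == en else 1.0 for t in all_tfs])
        tf_cols[s] = tf_base * fac * np.exp(rng.normal(0.0, sigma, len(all_tfs)))
    tf_expression = pd.DataFrame(tf_cols, index=all_tfs)

    truth = GroundTruth(
        driver_motif_id=driver.id,
        driver_peaks=list(peaks["name"].iloc[driver_idx]),
        coordinated_tads=pd.DataFrame(
            {"sign": [coord_sign[t] for t in coord_tads]}, index=coord_tads
        ),
        differential_tfs=pd.DataFrame(
            {"log2fc_en": [tf_lfc[t] for t in diff_tfs]}, index=diff_tfs
        ),
        promoter_motif_genes=[str(g) for g in promoter_motif_genes],
        up_genes=[str(g) for g in up_genes],
    )
    return RegulatoryLandscape(
        design=design,
        genome=genome,
        peaks=peaks[["chrom", "start", "end", "name", "tad"]],
        counts=counts,
        motifs=motifs,
        tads=tads,
        genes=genes,
        tf_expression=tf_expression,
        tf_map=tf_map,
        truth=truth,
    )


def make_gene_sets(
    truth: GroundTruth, universe: Sequence[str], n_decoy_sets: int = 10,
    decoy_size: int = 50, seed: int = 0,
) -> dict[str, list[str]]:
    """Synthetic signature gene sets: the planted EN-up genes plus random decoys."""
    rng = np.random.default_rng(seed)
    universe = list(universe)
    sets = {"EN_up_signature": [g for g in truth.up_genes if g in set(universe)]}
    for i in range(n_decoy_sets):
        sets[f"decoy_set_{i + 1:02d}"] = list(rng.choice(universe, size=decoy_size, replace=False))
    return sets


# ---------------------------------------------------------------------------
# on-disk study
# ---------------------------------------------------------------------------


def write_expression_study(study: ExpressionStudy, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    odio.write_matrix(study.protein_unfractionated, outdir / "protein_unfractionated.tsv")
    odio.write_matrix(study.protein_fractionated, outdir / "protein_fractionated.tsv")
    odio.write_matrix(study.counts, outdir / "mrna_counts.tsv")
    study.protein_panel.to_frame().to_csv(outdir / "protein_spikeins.tsv", sep="\t", index=False)
    study.ercc_panel.to_frame().to_csv(outdir / "ercc_spikeins.tsv", sep="\t", index=False)
    study.truth.to_json(outdir / "ground_truth_expression.json")


def write_landscape(landscape: RegulatoryLandscape, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    odio.write_fasta(landscape.genome.chromosomes, outdir / "genome.fa")
    odio.write_bed(landscape.peaks, outdir / "peaks.bed")
    odio.write_bed(landscape.tads, outdir / "tads.bed")
    tss = landscape.genes.reset_index()
    tss_bed = pd.DataFrame(
        {
            "chrom": tss["chrom"],
            "start": tss["tss"],
            "end": tss["tss"] + 1,
            "name": tss["gene"],
            "score": 0,
            "strand": tss["strand"],
        }
    )
    odio.write_bed(tss_bed, outdir / "tss.bed")
    odio.write_matrix(landscape.counts, outdir / "peak_counts.tsv", index_name="peak")
    odio.write_matrix(landscape.tf_expression, outdir / "tf_expression.tsv", index_name="tf")
    landscape.tf_map.to_csv(outdir / "motif_tf_map.tsv", sep="\t", index=False)
    odio.write_jaspar(landscape.motifs, outdir / "motifs.jaspar")
    landscape.truth.to_json(outdir / "ground_truth_landscape.json")
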