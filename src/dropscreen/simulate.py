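"""Synthetic dropout-screen generator.

Emulates a pooled negative-selection screen: a baseline barcode representation
drawn once per replicate, deterministic exponential depletion of hairpins
against planted essential genes over the selection period, and amplicon
sequencing with per-base substitution error.  Condition-specific essentials
let the three-setting comparison (untreated / drug / drug + conditioned media)
be exercised on known ground truth.

The selection model is intentionally simple: abundances evolve as
``a_i(t) ∝ a_i(0) * exp(-s_i * t)`` with ``s_i >= 0`` the per-day depletion
rate, and all stochasticity enters through the baseline draw and multinomial
sequencing sampling.  At 200-1000x coverage this captures the statistical
structure the downstream fold-change analysis assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import stats

from .library import IntegrityError, LibraryDesign, ParameterError

__all__ = [
    "EffectMap",
    "AbundanceProfile",
    "SampleRecord",
    "plant_effects",
    "simulate_baseline",
    "apply_selection",
    "emit_fastq",
    "simulate_screen",
    "simulate_screen_counts",
    "write_sample_sheet",
    "read_sample_sheet",
    "DEFAULT_FLANK_5",
    "DEFAULT_FLANK_3",
]

# Fixed amplicon flanks shared by simulator and quantifier (vector backbone
# context around the barcode); the quantifier locates the barcode at
# offset = len(DEFAULT_FLANK_5).
DEFAULT_FLANK_5 = "ACCGGTTAAGCGGAGATCCT"  # 20 nt
DEFAULT_FLANK_3 = "GTTTCGGATCCTAG"  # 14 nt

NEUTRAL = "neutral"
ESSENTIAL_ALL = "essential_all"
CONDITION_PREFIX = "essential_condition:"


@dataclass
class EffectMap:
    """Planted ground truth: per-hairpin depletion rates and per-gene labels.

    ``s`` is aligned with the design's record order (per-day rate, >0 means
    the hairpin depletes).  ``gene_labels`` maps every reliable gene to one of
    ``neutral``, ``essential_all`` or ``essential_condition:<name>``.
    """

    s: np.ndarray
    gene_labels: dict[str, str]
    effective_fraction: float
    design_complexity: int
    gene_rows: dict[str, list[int]] = field(default_factory=dict, repr=False)
    # Construct-intrinsic background fitness rates (off-target and mild
    # fitness effects, per day; may be negative = slight enrichment).  Shared
    # across replicates and settings — the "biology" replicates have in
    # common — while counting noise stays independent.  Zero for a clean map.
    s_background: np.ndarray | None = None

    def __post_init__(self):
        if self.s_background is None:
            self.s_background = np.zeros_like(self.s)

    @property
    def essential_genes(self) -> set[str]:
        return {g for g, lab in self.gene_labels.items() if lab != NEUTRAL}

    @property
    def neutral_genes(self) -> set[str]:
        return {g for g, lab in self.gene_labels.items() if lab == NEUTRAL}

    def condition_specific_genes(self, condition: str | None = None) -> set[str]:
        out = set()
        for g, lab in self.gene_labels.items():
            if lab.startswith(CONDITION_PREFIX):
                if condition is None or lab == CONDITION_PREFIX + condition:
                    out.add(g)
        return out


@dataclass
class AbundanceProfile:
    """Relative hairpin abundances (sum to 1) at a time point in a condition."""

    abundance: np.ndarray
    day: float = 0.0
    condition: str = "baseline"

    def __post_init__(self):
        a = np.asarray(self.abundance, dtype=float)
        if (a < 0).any():
            raise ParameterError("abundances must be nonnegative")
        if abs(a.sum() - 1.0) > 1e-9:
            raise ParameterError(f"abundances must sum to 1 (got {a.sum():.12f})")
        self.abundance = a


@dataclass
class SampleRecord:
    """One sequenced sample with its screen metadata."""

    sample_id: str
    condition: str  # "baseline" or a setting label
    replicate: int
    transduction_efficiency: float | None = None
    fastq_path: str | None = None

    @property
    def is_baseline(self) -> bool:
        return self.condition == "baseline"


def plant_effects(
    design: LibraryDesign,
    fraction_essential: float = 0.05,
    fraction_condition_specific: float = 0.0,
    s_distribution: tuple[float, float] = (0.5, 0.15),
    effective_fraction: float = 0.8,
    condition_specific_label: str = "setting3",
    background_sd: float = 0.03,
    seed: int = 0,
) -> EffectMap:
    """Label a seeded random subset of reliable genes essential and draw rates.

    ``floor(fraction_essential * n_reliable)`` genes become essential; of
    those, ``floor(fraction_condition_specific * n_essential)`` are essential
    only under ``condition_specific_label``.  For each essential gene,
    ``ceil(effective_fraction * n_shRNAs)`` of its hairpins receive a depletion
    rate drawn from a normal truncated at zero; all other hairpins get s=0.

    Independently of gene labels, every hairpin receives a small background
    fitness rate drawn from Normal(0, ``background_sd``) per day — the
    construct-intrinsic (off-target and mild fitness) effects that replicate
    experiments share while their sampling noise stays independent.  Set
    ``background_sd=0`` for an effect map with no shared background.
    """
    if background_sd < 0:
        raise ParameterError("background_sd must be nonnegative")
    for name, frac in [("fraction_essential", fraction_essential),
                       ("fraction_condition_specific", fraction_condition_specific),
                       ("effective_fraction", effective_fraction)]:
        if not 0.0 <= frac <= 1.0:
            raise ParameterError(f"{name} must be in [0, 1], got {frac}")
    mean, sd = s_distribution
    if fraction_essential > 0 and mean <= 0:
        raise ParameterError("s_distribution mean must be > 0")

    rng = np.random.default_rng(seed)
    reliable = design.reliable_genes
    n_ess = int(math.floor(fraction_essential * len(reliable)))
    order = rng.permutation(len(reliable))
    essential = [reliable[i] for i in order[:n_ess]]
    n_cond = int(math.floor(fraction_condition_specific * n_ess))
    cond_specific = set(essential[:n_cond])

    labels = {g: NEUTRAL for g in reliable}
    for g in essential:
        labels[g] = (CONDITION_PREFIX + condition_specific_label
                     if g in cond_specific else ESSENTIAL_ALL)

    s = np.zeros(design.complexity)
    for g in essential:
        rows = design.rows_for_gene(g)
        n_eff = int(math.ceil(effective_fraction * len(rows)))
        chosen = rng.choice(len(rows), size=n_eff, replace=False)
        if sd > 0:
            a = -mean / sd  # truncate at zero
            draws = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                        size=n_eff, random_state=rng)
        else:
            draws = np.full(n_eff, mean)
        for j, d in zip(chosen, draws):
            s[rows[j]] = d
    s_background = (rng.normal(0.0, background_sd, size=design.complexity)
                    if background_sd > 0 else np.zeros(design.complexity))
    return EffectMap(s=s, gene_labels=labels,
                     effective_fraction=effective_fraction,
                     design_complexity=design.complexity,
                     gene_rows={g: design.rows_for_gene(g) for g in reliable},
                     s_background=s_background)


def simulate_baseline(design: LibraryDesign, dispersion: float = 0.3,
                      seed: int = 0) -> AbundanceProfile:
    """Draw baseline representation from a symmetric Dirichlet.

    Concentration 1/dispersion: small dispersion gives near-uniform
    representation (complete library coverage), large dispersion a skewed one.
    """
    if dispersion <= 0:
        raise ParameterError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    alpha = np.full(design.complexity, 1.0 / dispersion)
    a = rng.dirichlet(alpha)
    a = np.maximum(a, 1e-300)
    a = a / a.sum()
    return AbundanceProfile(abundance=a, day=0.0, condition="baseline")


def _active_rates(effects: EffectMap, condition: str) -> np.ndarray:
    """Per-hairpin rates acting in the given condition.

    Planted essential effects are gated by gene label; the background
    component acts in every selection condition.
    """
    s = effects.s_background.copy()
    for gene, label in effects.gene_labels.items():
        if label == ESSENTIAL_ALL or label == CONDITION_PREFIX + condition:
            rows = effects.gene_rows.get(gene, [])
            s[rows] += effects.s[rows]
    return s


def apply_selection(profile: AbundanceProfile, effects: EffectMap,
                    days: float, condition: str) -> AbundanceProfile:
    """Deplete hairpins exponentially: a_i ∝ a_i * exp(-s_i * days).

    Condition-specific effects act only when ``condition`` matches their
    gene's label; the result is renormalized and the clock advanced.
    """
    if len(profile.abundance) != effects.design_complexity:
        raise IntegrityError(
            f"profile has {len(profile.abundance)} entries but effects were "
            f"planted on a design of complexity {effects.design_complexity}"
        )
    if days < 0:
        raise ParameterError("days must be nonnegative")
    s = _active_rates(effects, condition)
    w = profile.abundance * np.exp(-s * days)
    w = w / w.sum()
    return AbundanceProfile(abundance=w, day=profile.day + days, condition=condition)


def emit_fastq(
    profile: AbundanceProfile,
    design: LibraryDesign,
    n_reads: int,
    error_rate: float = 0.0,
    flank_5: str = DEFAULT_FLANK_5,
    flank_3: str = DEFAULT_FLANK_3,
    seed: int = 0,
    path=None,
) -> np.ndarray:
    """Write amplicon reads (flank + barcode + flank) and return the truth tally.

    Each read's barcode is drawn multinomially from the profile, then i.i.d.
    per-base substitutions are applied at ``error_rate`` over the whole read.
    Qualities are constant 'I' (Phred 40).  The returned vector is the exact
    per-hairpin count of reads drawn from each barcode *before* errors — the
    ground-truth tally used as an oracle for the quantifier.
    """
    if not 0.0 <= error_rate <= 0.2:
        raise ParameterError("error_rate must be in [0, 0.2]")
    if design.complexity == 0:
        raise ParameterError("cannot emit reads from an empty design")
    if n_reads < 0:
        raise ParameterError("n_reads must be nonnegative")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, profile.abundance)

    # Assemble reads vectorized as a byte matrix.
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    bc_mat = np.frombuffer("".join(design.barcodes).encode(), dtype=np.uint8)
    bc_mat = bc_mat.reshape(design.complexity, design.barcode_length) if design.complexity else bc_mat
    idx = np.repeat(np.arange(design.complexity), counts)
    rng.shuffle(idx)
    read_len = len(flank_5) + design.barcode_length + len(flank_3)
    reads = np.empty((n_reads, read_len), dtype=np.uint8)
    reads[:, : len(flank_5)] = np.frombuffer(flank_5.encode(), dtype=np.uint8)
    reads[:, len(flank_5): len(flank_5) + design.barcode_length] = bc_mat[idx]
    reads[:, len(flank_5) + design.barcode_length:] = np.frombuffer(flank_3.encode(), dtype=np.uint8)

    if error_rate > 0 and n_reads > 0:
        err = rng.random((n_reads, read_len)) < error_rate
        n_err = int(err.sum())
        if n_err:
            # substitute with a uniformly random *different* base
            cur = reads[err]
            cur_idx = np.searchsorted(bases, cur)
            shift = rng.integers(1, 4, size=n_err)
            reads[err] = bases[(cur_idx + shift) % 4]

    if path is not None:
        qual = "I" * read_len
        with open(path, "w") as fh:
            buf = []
            for i in range(n_reads):
                buf.append(f"@read{i + 1}\n{reads[i].tobytes().decode()}\n+\n{qual}\n")
                if len(buf) >= 10000:
                    fh.write("".join(buf))
                    buf = []
            fh.write("".join(buf))
    return counts


def write_sample_sheet(samples: list[SampleRecord], path) -> None:
    """FASTQ paths are stored relative to the sheet's directory when possible,
    so a run directory is relocatable and byte-reproducible."""
    base = Path(path).parent.resolve()
    with open(path, "w") as fh:
        fh.write("sample_id\tcondition\treplicate\ttransduction_efficiency\tfastq_path\n")
        for s in samples:
            te = "" if s.transduction_efficiency is None else f"{s.transduction_efficiency:.4f}"
            fq = s.fastq_path or ""
            if fq:
                try:
                    fq = str(Path(fq).resolve().relative_to(base))
                except ValueError:
                    pass  # outside the sheet directory: keep as given
            fh.write(f"{s.sample_id}\t{s.condition}\t{s.replicate}\t{te}\t{fq}\n")


def read_sample_sheet(path) -> list[SampleRecord]:
    samples = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["sample_id", "condition", "replicate",
                    "transduction_efficiency", "fastq_path"]
        if header != expected:
            raise ParameterError(f"sample sheet header must be {expected}, got {header}")
        base = Path(path).parent
        for line in fh:
            if not line.strip():
                continue
            sid, cond, rep, te, fq = line.rstrip("\n").split("\t")
            if fq and not Path(fq).is_absolute():
                fq = str(base / fq)
            samples.append(SampleRecord(
                sample_id=sid, condition=cond, replicate=int(rep),
                transduction_efficiency=float(te) if te else None,
                fastq_path=fq or None))
    return samples


def _screen_profiles(design, effects, settings, replicates, days,
                     dispersion, te_interval, seed):
    """Shared scaffolding: per-replicate baseline + per-setting selection."""
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    out = []  # (sample_record_stub, profile)
    for rep in range(1, replicates + 1):
        base = simulate_baseline(design, dispersion=dispersion,
                                 seed=int(rng.integers(0, 2 ** 31)))
        te = float(rng.uniform(*te_interval))
        out.append((SampleRecord(f"baseline_rep{rep}", "baseline", rep, None), base))
        for setting in settings:
            sel = apply_selection(base, effects, days, setting)
            out.append((SampleRecord(f"{setting}_rep{rep}", setting, rep, te), sel))
    return out, rng


def simulate_screen(
    design: LibraryDesign,
    effects: EffectMap,
    settings: list[str],
    replicates: int = 2,
    days: float = 9.0,
    n_reads: int = 500_000,
    error_rate: float = 0.005,
    dispersion: float = 0.3,
    te_interval: tuple[float, float] = (0.15, 0.35),
    seed: int = 0,
    outdir=".",
) -> tuple[list[SampleRecord], dict[str, np.ndarray]]:
    """Full screen: FASTQ per sample plus a sample sheet.

    Each replicate draws an independent baseline shared across its settings
    (the snap-frozen control), applies the selection per setting, and
    sequences every sample.  Returns the sample records (with FASTQ paths)
    and the per-sample ground-truth read tallies.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stubs, rng = _screen_profiles(design, effects, settings, replicates, days,
                                  dispersion, te_interval, seed)
    samples, truth = [], {}
    for stub, profile in stubs:
        fq = outdir / f"{stub.sample_id}.fastq"
        counts = emit_fastq(profile, design, n_reads, error_rate,
                            seed=int(rng.integers(0, 2 ** 31)), path=fq)
        samples.append(replace(stub, fastq_path=str(fq)))
        truth[stub.sample_id] = counts
    write_sample_sheet(samples, outdir / "samples.tsv")
    return samples, truth


def simulate_screen_counts(
    design: LibraryDesign,
    effects: EffectMap,
    settings: list[str],
    replicates: int = 2,
    days: float = 9.0,
    n_reads: int = 500_000,
    error_rate: float = 0.005,
    dispersion: float = 0.3,
    te_interval: tuple[float, float] = (0.15, 0.35),
    seed: int = 0,
) -> tuple[list[SampleRecord], dict[str, np.ndarray]]:
    """Count-level screen: multinomial sequencing without read emission.

    Statistically equivalent to sequencing + mismatch-tolerant quantification:
    reads whose barcode acquires >= 2 substitutions are unrecoverable and are
    dropped by binomial thinning; 0- and 1-error reads are assigned correctly
    (the distance-2 barcode code guarantees 1-error reads stay nearest their
    true barcode).  Used for large parameter-recovery studies.
    """
    stubs, rng = _screen_profiles(design, effects, settings, replicates, days,
                                  dispersion, te_interval, seed)
    L = design.barcode_length
    e = error_rate
    p_keep = (1 - e) ** L + L * e * (1 - e) ** (L - 1)
    samples, counts = [], {}
    for stub, profile in stubs:
        c = rng.multinomial(n_reads, profile.abundance)
        if e > 0:
            c = rng.binomial(c, p_keep)
        samples.append(stub)
        counts[stub.sample_id] = c
    return samples, counts
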