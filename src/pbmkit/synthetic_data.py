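"""Synthetic PBM experiments, motif-planted sequence sets and titrations.

The generator emulates the design of a two-colour protein-binding microarray
study of a transcription factor probed against a library of ~6000 human
regulatory fragments of ~1000 bp (the hu6k design): every sequence spotted 20
times per slide at different positions, 3 replicate slides for the purified
protein, and a 4-healthy / 8-tumor slide design for tissue extracts.  Each
simulated dataset carries a :class:`GroundTruth` recording every planted
effect, so recovery, FDR and calibration can be measured exactly.

Signal model (per spot, log2 scale):

    red  = DNA amount: lognormal per sequence (sd ``dna_log2_sd``, spanning
           the A range) times per-spot deposition jitter
           (sd ``deposition_log2_sd``, setting the replicate-spot CV)
    green = red * 2^(true_M + dye_bias(A) + slide_effect + noise)

where ``true_M`` is the planted binding effect of the sequence (plus a signed
group-2 differential effect for differential sequences), ``dye_bias`` is a
smooth sinusoid-plus-trend in spot intensity scaled by
``dye_bias_amplitude``, ``slide_effect`` ~ N(0, slide_scale_sd) is a per-slide
offset, and ``noise`` ~ N(0, spot_noise_sd) is multiplicative (lognormal)
spot noise.  Backgrounds are a small constant fraction of the foreground,
perturbed only when spot noise is on, so the zero-noise configuration
recovers every planted M exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ContractError
from .io_formats import ArraySet, SequenceRecord, Slide, SpotRecord, write_fasta, write_gpr
from .motif_scan import MotifMatrix, reverse_complement
from .affinity import TitrationSeries

__all__ = [
    "PbmSimConfig",
    "GroundTruth",
    "simulate_pbm_experiment",
    "simulate_sequences_with_sites",
    "simulate_titration",
    "write_experiment",
]

#: mean log2 DNA amount per spot (arbitrary fluorescence units, ~10 bits)
_BASE_LOG2_INTENSITY = 10.0
#: background as a fraction of foreground
_BG_FRACTION = 0.05


@dataclass
class PbmSimConfig:
    """Configuration of a simulated PBM experiment.

    Defaults mirror the emulated study: ~6000 sequences of ~1000 bp, 20
    replicate spots per sequence, and a two-group tissue design with 4
    healthy and 8 tumor slides.  Effects and noise terms are in log2 units.

    Notes
    -----
    ``slides_per_group`` may be a single count or one count per group (the
    emulated tissue design is unbalanced: 4 vs 8).  ``frac_bound`` sequences
    receive a true binding effect of ``bound_effect``; ``frac_differential``
    sequences additionally differ between groups by ``differential_effect``
    with random sign, applied to group 2 only.
    """

    n_sequences: int = 6000
    seq_length: int = 1000
    spots_per_sequence: int = 20
    slides_per_group: int | tuple[int, ...] = (4, 8)
    n_groups: int = 2
    frac_bound: float = 0.05
    bound_effect: float = 1.0
    frac_differential: float = 0.05
    differential_effect: float = 1.0
    dye_bias_amplitude: float = 0.5
    slide_scale_sd: float = 0.1
    spot_noise_sd: float = 0.25
    dna_log2_sd: float = 0.5
    deposition_log2_sd: float = 0.05
    group_names: tuple[str, ...] = ("normal", "cancer")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_bound", "frac_differential"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_sequences", "seq_length", "spots_per_sequence"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive count")
        if self.n_groups not in (1, 2):
            raise ConfigurationError("n_groups must be 1 or 2")
        if isinstance(self.slides_per_group, int):
            self.slides_per_group = (self.slides_per_group,) * self.n_groups
        else:
            self.slides_per_group = tuple(self.slides_per_group)
        if len(self.slides_per_group) != self.n_groups:
            raise ConfigurationError(
                "slides_per_group must give one count per group"
            )
        if any(n < 1 for n in self.slides_per_group):
            raise ConfigurationError("slide counts must be positive")
        for name in (
            "dye_bias_amplitude",
            "slide_scale_sd",
            "spot_noise_sd",
            "dna_log2_sd",
            "deposition_log2_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if len(self.group_names) < self.n_groups:
            raise ConfigurationError("need a name for every group")

    @classmethod
    def from_yaml(cls, path) -> "PbmSimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("slides_per_group", "group_names"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted truth of a simulated dataset.

    ``effects`` maps sequence id to the true binding effect (log2),
    ``differential`` to the signed group-2 differential effect (0 when the
    sequence is not differential).  ``site_positions`` records planted motif
    sites as (position, strand); ``kd`` records true dissociation constants
    of simulated titrations.
    """

    effects: dict[str, float] = field(default_factory=dict)
    differential: dict[str, float] = field(default_factory=dict)
    site_positions: dict[str, tuple[int, str]] = field(default_factory=dict)
    kd: dict[str, float] = field(default_factory=dict)

    @property
    def bound_ids(self) -> set[str]:
        return {s for s, e in self.effects.items() if e != 0.0}

    @property
    def differential_ids(self) -> set[str]:
        return {s for s, e in self.differential.items() if e != 0.0}

    def to_frame(self) -> pd.DataFrame:
        ids = sorted(set(self.effects) | set(self.differential))
        return pd.DataFrame(
            {
                "sequence_id": ids,
                "true_effect": [self.effects.get(i, 0.0) for i in ids],
                "true_differential": [self.differential.get(i, 0.0) for i in ids],
            }
        )


def _dye_bias(a0: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth sinusoid-plus-trend bias as a function of spot intensity.

    Any smooth shape exercises the loess correction equally; this one mixes
    one sine period with a linear trend over the observed intensity range.
    """
    if amplitude == 0.0:
        return np.zeros_like(a0)
    spread = np.ptp(a0)
    if spread == 0.0:
        return np.zeros_like(a0)
    u = (a0 - a0.min()) / spread
    return amplitude * (0.6 * np.sin(2.0 * np.pi * u) + 0.4 * (2.0 * u - 1.0))


def simulate_pbm_experiment(config: PbmSimConfig) -> tuple[ArraySet, GroundTruth]:
    """Simulate a spot-level PBM experiment with recorded ground truth.

    Returns an :class:`ArraySet` (one slide per replicate, grouped) whose
    spot records are ready for the normalization chain, and the
    :class:`GroundTruth` of every planted effect.  Fixing ``config.seed``
    fixes every emitted byte.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sequences
    seq_ids = [f"seq{i:05d}" for i in range(n)]

    n_bound = int(round(config.frac_bound * n))
    bound_idx = rng.choice(n, size=n_bound, replace=False)
    effects = np.zeros(n)
    effects[bound_idx] = config.bound_effect

    diff_effects = np.zeros(n)
    if config.n_groups == 2:
        n_diff = int(round(config.frac_differential * n))
        diff_idx = rng.choice(n, size=n_diff, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_diff)
        diff_effects[diff_idx] = signs * config.differential_effect

    truth = GroundTruth(
        effects=dict(zip(seq_ids, effects.tolist())),
        differential=dict(zip(seq_ids, diff_effects.tolist())),
    )

    # fixed spot layout shared by all slides: a random permutation of
    # sequence replicates over a rectangular grid
    k = config.spots_per_sequence
    n_spots = n * k
    layout = rng.permutation(np.repeat(np.arange(n), k))
    n_cols = int(np.ceil(np.sqrt(n_spots)))

    arrays = ArraySet()
    for group_index in range(config.n_groups):
        group = config.group_names[group_index]
        true_m = effects + (diff_effects if group_index == 1 else 0.0)
        for rep in range(config.slides_per_group[group_index]):
            slide_id = f"{group}_{rep + 1}"
            slide_effect = (
                rng.normal(0.0, config.slide_scale_sd)
                if config.slide_scale_sd > 0
                else 0.0
            )
            # DNA amount: a per-sequence level (spans the A range, since all
            # replicates of a sequence come from one source well) plus small
            # per-spot deposition jitter (sets the replicate CV)
            seq_level = (
                rng.normal(0.0, config.dna_log2_sd, size=n)
                if config.dna_log2_sd > 0
                else np.zeros(n)
            )
            deposition = (
                rng.normal(0.0, config.deposition_log2_sd, size=n_spots)
                if config.deposition_log2_sd > 0
                else np.zeros(n_spots)
            )
            log2_red = _BASE_LOG2_INTENSITY + seq_level[layout] + deposition
            noise = (
                rng.normal(0.0, config.spot_noise_sd, size=n_spots)
                if config.spot_noise_sd > 0
                else np.zeros(n_spots)
            )
            bias = _dye_bias(log2_red, config.dye_bias_amplitude)
            red = 2.0**log2_red
            green = red * 2.0 ** (true_m[layout] + bias + slide_effect + noise)

            red_fg = red / (1.0 - _BG_FRACTION)
            green_fg = green / (1.0 - _BG_FRACTION)
            if config.spot_noise_sd > 0:
                # independent per-channel jitter so background subtraction
                # actually perturbs the ratio
                jr = np.clip(1.0 + 0.2 * config.spot_noise_sd * rng.normal(size=n_spots), 0.0, 2.0)
                jg = np.clip(1.0 + 0.2 * config.spot_noise_sd * rng.normal(size=n_spots), 0.0, 2.0)
            else:
                jr = jg = np.ones(n_spots)
            red_bg = _BG_FRACTION * red_fg * jr
            green_bg = _BG_FRACTION * green_fg * jg

            spots = [
                SpotRecord(
                    slide_id=slide_id,
                    block=1,
                    column=int(j % n_cols) + 1,
                    row=int(j // n_cols) + 1,
                    sequence_id=seq_ids[layout[j]],
                    red_fg=float(red_fg[j]),
                    red_bg=float(red_bg[j]),
                    green_fg=float(green_fg[j]),
                    green_bg=float(green_bg[j]),
                )
                for j in range(n_spots)
            ]
            arrays.slides.append(Slide(slide_id=slide_id, group=group, spots=spots))
    return arrays, truth


def simulate_sequences_with_sites(
    n: int,
    length: int,
    pwm: MotifMatrix,
    planting_rate: float,
    seed: int = 0,
) -> tuple[list[SequenceRecord], GroundTruth]:
    """Uniform-random DNA with the PWM's consensus planted in some sequences.

    A ``planting_rate`` fraction of sequences receives the matrix's
    maximal-score word at a recorded position and strand (minus-strand plants
    insert the reverse complement, so rescanning recovers the same maximal
    score on the recorded strand).
    """
    if not 0.0 <= planting_rate <= 1.0:
        raise ConfigurationError(f"planting_rate must be in [0, 1], got {planting_rate}")
    if n < 1 or length < 1:
        raise ConfigurationError("n and length must be positive")
    if length < pwm.width:
        raise ContractError(
            f"sequence length {length} shorter than PWM width {pwm.width}"
        )
    rng = np.random.default_rng(seed)
    n_planted = int(round(planting_rate * n))
    planted = np.zeros(n, dtype=bool)
    planted[rng.choice(n, size=n_planted, replace=False)] = True

    consensus = pwm.consensus
    records: list[SequenceRecord] = []
    truth = GroundTruth()
    bases = np.array(list("ACGT"))
    for i in range(n):
        seq = "".join(bases[rng.integers(0, 4, size=length)])
        seq_id = f"rseq{i:05d}"
        if planted[i]:
            pos = int(rng.integers(0, length - pwm.width + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            word = consensus if strand == "+" else reverse_complement(consensus)
            seq = seq[:pos] + word + seq[pos + pwm.width :]
            truth.site_positions[seq_id] = (pos, strand)
        records.append(SequenceRecord(id=seq_id, sequence=seq))
    return records, truth


def simulate_titration(
    kd: float,
    rmax: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
    sequence_id: str = "titration",
) -> TitrationSeries:
    """Langmuir responses R = rmax*C/(kd+C) with multiplicative noise.

    ``noise_sd`` is the relative (fractional) SD of the multiplicative noise
    term, emulating equilibrium-plateau read-out error.
    """
    if kd <= 0 or rmax <= 0:
        raise ConfigurationError("kd and rmax must be positive")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    c = np.asarray(concentrations, dtype=float)
    if (c < 0).any():
        raise ConfigurationError("concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    response = rmax * c / (kd + c)
    if noise_sd > 0:
        response = response * (1.0 + noise_sd * rng.standard_normal(c.size))
    return TitrationSeries(sequence_id=sequence_id, concentrations=c, responses=response)


def write_experiment(
    arrays: ArraySet, truth: GroundTruth, outdir, sequences: list[SequenceRecord] | None = None
) -> dict[str, str]:
    """Write GPR files (one per slide), the ground-truth table and FASTA.

    Returns a manifest mapping output names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for slide in arrays.slides:
        path = outdir / f"{slide.slide_id}.gpr"
        write_gpr(slide.spots, path)
        manifest[slide.slide_id] = str(path)
    truth_path = outdir / "ground_truth.tsv"
    truth.to_frame().to_csv(truth_path, sep="\t", index=False)
    manifest["ground_truth"] = str(truth_path)
    if sequences is not None:
        fasta_path = outdir / "sequences.fasta"
        write_fasta(sequences, fasta_path)
        manifest["sequences"] = str(fasta_path)
    return manifest
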