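"""Synthetic gumfoot datasets with known ground truth.

Every downstream stage — droplet mechanics, LFQ enrichment, PTM contingency
tables, sequence properties, gland expression — can be exercised end to end
without the original measurement videos or mass-spectrometry deposits.

The droplet simulator works by *inverting* the mechanics: it fixes a target
linear true stress-true strain law (sigma = sigma_0 + E * eps), chooses the
droplet length at each extension interval, computes the stress (hence
force) that length implies, and solves for the support-line deflection
angle delivering that force. Running the emitted series back through the
mechanics module at zero angle noise therefore recovers the generating
modulus exactly — recovery is an identity by construction, and angle noise
is the only corrupting influence.

Defaults describe a mid-range synthetic testbed: a core-rich droplet
(core fraction 0.69 of droplet volume, the two-species average) on a
two-fiber support line whose stiffness puts deflection angles in the
well-conditioned 10-50 degree band (the humid, supercontracted-fiber
regime; see docs/methods.md for why the stiff dry-fiber regime is
hostile to angle-noise recovery).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import mechanics
from .enrichment import FIBER, GLUE_FIBER, LFQMatrix
from .mechanics import (
    DropletGeometry,
    ExtensionSeries,
    MaterialProperties,
    SupportLine,
)

__all__ = [
    "DropletSimConfig",
    "LFQSimConfig",
    "PTMSimConfig",
    "UnsatisfiableConfigurationError",
    "generate_droplet_experiment",
    "generate_lfq_dataset",
    "generate_ptm_peptide_table",
    "generate_protein_sequences",
    "generate_gland_tpm",
    "SEQUENCE_PRESETS",
    "GLAND_TYPES",
]


class UnsatisfiableConfigurationError(ValueError):
    """The requested stress law needs a deflection the fibers cannot give."""


# ---------------------------------------------------------------------------
# droplet extension experiments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DropletSimConfig:
    """Ground truth and measurement setup for one simulated extension trial.

    ``true_modulus`` and ``initial_stress`` define the linear stress-strain
    law; ``max_strain`` is the total true strain at pull-off. Geometry
    follows the suspended-droplet volume formula with ``core_fraction`` of
    the droplet volume being adhesive core. ``angle_noise_sd`` (degrees) is
    added to every deflection angle after the exact inversion.
    """

    seed: int = 0
    true_modulus: float = 1.5  # MPa
    initial_stress: float = 0.1  # MPa
    droplet_length_DL: float = 100.0  # um
    droplet_width_DW: float = 60.0  # um
    core_fraction: float = 0.69
    fiber_count: int = 2
    fiber_diameter: float = 2.5  # um
    fiber_modulus: float = 800.0  # MPa
    span: float = 4800.0  # um
    angle_noise_sd: float = 0.0  # degrees
    n_intervals: int = 6
    max_strain: float = 1.2

    def __post_init__(self) -> None:
        if not (0.0 < self.core_fraction <= 1.0):
            raise ValueError("core_fraction must lie in (0, 1]")
        for name in ("droplet_length_DL", "droplet_width_DW", "fiber_diameter",
                     "fiber_modulus", "span", "max_strain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.angle_noise_sd < 0:
            raise ValueError("angle_noise_sd must be non-negative")
        if self.n_intervals < 2:
            raise ValueError("need at least two extension intervals")
        if self.initial_stress < 0 or self.true_modulus <= 0:
            raise ValueError("stresses must be non-negative, modulus positive")


_THETA_MAX = 89.0  # degrees; beyond this the configuration is unsatisfiable


def _solve_deflection(force: float, line: SupportLine) -> float:
    """Deflection angle (degrees) at which the line delivers ``force``."""
    if force == 0.0:
        return 0.0
    f = lambda th: mechanics.droplet_force(th, line) - force
    if f(_THETA_MAX) < 0:
        raise UnsatisfiableConfigurationError(
            f"force {force:.3g} uN requires deflection >= {_THETA_MAX} deg; "
            "support line too compliant for the requested stress law"
        )
    return float(brentq(f, 0.0, _THETA_MAX, xtol=1e-12))


def generate_droplet_experiment(
    config: DropletSimConfig,
) -> tuple[SupportLine, DropletGeometry, ExtensionSeries, MaterialProperties]:
    """Simulate one droplet extension trial with known material properties.

    Returns the support line, droplet geometry, the (possibly noisy)
    extension series, and the ground-truth properties. At
    ``angle_noise_sd = 0`` the mechanics pipeline recovers
    ``config.true_modulus`` exactly on any fitted window.
    """
    rng = np.random.default_rng(config.seed)

    line = SupportLine(
        fiber_count=config.fiber_count,
        fiber_diameter=config.fiber_diameter,
        fiber_modulus=config.fiber_modulus,
        span=config.span,
    )

    DV = mechanics.droplet_volume(config.droplet_length_DL, config.droplet_width_DW)
    # flattened thickness fixed at DW/3 (a squat flattened dome); the
    # flattened areas then follow from DV and the core fraction
    thickness = config.droplet_width_DW / 3.0
    flattened_area = DV / thickness
    core_area = config.core_fraction * flattened_area
    geom = mechanics.droplet_geometry(
        config.droplet_length_DL,
        config.droplet_width_DW,
        flattened_area,
        core_area,
    )

    L0 = mechanics.initial_filament_length(geom.core_volume, "radius")
    fractions = np.linspace(0.0, 1.0, config.n_intervals)
    strains = config.max_strain * fractions
    lengths = L0 * np.exp(strains)
    stresses = config.initial_stress + config.true_modulus * strains

    angles = []
    for eps, L, sigma in zip(strains, lengths, stresses):
        force = sigma * mechanics.filament_csa(geom.core_volume, L)
        angles.append(_solve_deflection(force, line))
    angles = np.asarray(angles)

    if config.angle_noise_sd > 0:
        noisy = angles + rng.normal(0.0, config.angle_noise_sd, angles.size)
        # keep angles physical; intervals after the first stay strictly >0
        noisy[0] = min(max(noisy[0], 0.0), _THETA_MAX)
        noisy[1:] = np.clip(noisy[1:], 1e-6, _THETA_MAX)
        angles = noisy

    series = ExtensionSeries(
        fractions=tuple(float(f) for f in fractions),
        lengths=tuple(float(L) for L in lengths),
        angles=tuple(float(a) for a in angles),
    )
    # trapezoid area is exact for the linear generating law
    truth_toughness = config.true_modulus * config.max_strain**2 / 2.0
    truth = MaterialProperties(
        elastic_modulus=config.true_modulus,
        toughness=truth_toughness,
        modulus_window=(0.0, 1.0),
    )
    return line, geom, series, truth


# ---------------------------------------------------------------------------
# LFQ matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LFQSimConfig:
    """Design of a simulated two-run LFQ experiment.

    Log-normal abundances: a per-protein baseline (log scale) plus a batch
    offset for run 2, plus ``log_effect_size`` for glue-labeled proteins in
    GlueFiber samples, plus N(0, noise_sd) noise, exponentiated; zeros are
    then injected at ``dropout_rate`` to mimic missingness. The default
    sample design is run 1: 3 GlueFiber + 3 Fiber, run 2: 3 GlueFiber + 2
    Fiber (six versus five, the post-outlier house-spider design).
    """

    seed: int = 0
    n_proteins: int = 200
    n_glue_proteins: int = 30
    n_gf_samples: tuple[int, ...] = (3, 3)
    n_fiber_samples: tuple[int, ...] = (3, 2)
    log_effect_size: float = 3.0
    noise_sd: float = 0.5
    dropout_rate: float = 0.0
    run_shift: float = 0.3
    baseline_mean: float = 14.0
    baseline_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.n_glue_proteins > self.n_proteins:
            raise ValueError("n_glue_proteins cannot exceed n_proteins")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValueError("dropout_rate must lie in [0, 1]")
        if len(self.n_gf_samples) != len(self.n_fiber_samples):
            raise ValueError("per-run sample counts must cover the same runs")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be non-negative")


def generate_lfq_dataset(config: LFQSimConfig) -> tuple[LFQMatrix, pd.Series]:
    """Simulate an LFQ matrix and the boolean glue-protein truth labels."""
    rng = np.random.default_rng(config.seed)

    proteins = [f"P{i:04d}" for i in range(config.n_proteins)]
    is_glue = pd.Series(
        [i < config.n_glue_proteins for i in range(config.n_proteins)],
        index=proteins,
        name="is_glue",
    )

    sample_ids, types, runs = [], [], []
    for run_idx, (n_gf, n_f) in enumerate(
        zip(config.n_gf_samples, config.n_fiber_samples), start=1
    ):
        for j in range(n_gf):
            sample_ids.append(f"GF_r{run_idx}_{j + 1}")
            types.append(GLUE_FIBER)
            runs.append(run_idx)
        for j in range(n_f):
            sample_ids.append(f"F_r{run_idx}_{j + 1}")
            types.append(FIBER)
            runs.append(run_idx)
    samples = pd.DataFrame(
        {"sample_type": types, "run": runs}, index=pd.Index(sample_ids, name="sample_id")
    )

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_proteins)
    log_vals = np.empty((config.n_proteins, len(sample_ids)))
    for s_idx, sid in enumerate(sample_ids):
        mu = baseline + config.run_shift * (runs[s_idx] - 1)
        if types[s_idx] == GLUE_FIBER:
            mu = mu + config.log_effect_size * is_glue.to_numpy()
        log_vals[:, s_idx] = mu + rng.normal(0.0, config.noise_sd, config.n_proteins)
    values = np.exp(log_vals)
    dropout = rng.random(values.shape) < config.dropout_rate
    values[dropout] = 0.0

    run_labels = sorted(set(runs))
    scores = pd.DataFrame(
        rng.uniform(60.0, 300.0, (config.n_proteins, len(run_labels))),
        index=proteins,
        columns=run_labels,
    )
    matrix = LFQMatrix(
        values=pd.DataFrame(values, index=proteins, columns=sample_ids),
        samples=samples,
        scores=scores,
    )
    return matrix, is_glue


# ---------------------------------------------------------------------------
# PTM peptide tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PTMSimConfig:
    """Per-sample peptide modification rates for the two sample types.

    Glycosylation and phosphorylation are drawn independently per peptide
    (Bernoulli at the type-specific rate), so the both-modified category
    occurs at the product rate.
    """

    seed: int = 0
    peptides_per_sample: int = 1000
    n_gf_samples: int = 6
    n_fiber_samples: int = 6
    glyc_rate_gf: float = 0.11
    phos_rate_gf: float = 0.045
    glyc_rate_f: float = 0.015
    phos_rate_f: float = 0.008

    def __post_init__(self) -> None:
        for name in ("glyc_rate_gf", "phos_rate_gf", "glyc_rate_f", "phos_rate_f"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.peptides_per_sample < 0:
            raise ValueError("peptides_per_sample must be non-negative")


def generate_ptm_peptide_table(config: PTMSimConfig) -> pd.DataFrame:
    """Per-sample peptide table: peptide_id, sample_id, sample_type, flags."""
    rng = np.random.default_rng(config.seed)
    rows = []
    designs = [(GLUE_FIBER, "GF", config.n_gf_samples,
                config.glyc_rate_gf, config.phos_rate_gf),
               (FIBER, "F", config.n_fiber_samples,
                config.glyc_rate_f, config.phos_rate_f)]
    for stype, tag, n_samples, g_rate, p_rate in designs:
        for s in range(n_samples):
            sid = f"{tag}_{s + 1}"
            g = rng.random(config.peptides_per_sample) < g_rate
            p = rng.random(config.peptides_per_sample) < p_rate
            for k in range(config.peptides_per_sample):
                rows.append((f"{sid}_pep{k:05d}", sid, stype, bool(g[k]), bool(p[k])))
    return pd.DataFrame(
        rows,
        columns=["peptide_id", "sample_id", "sample_type",
                 "glycosylated", "phosphorylated"],
    )


# ---------------------------------------------------------------------------
# protein sequences and gland expression
# ---------------------------------------------------------------------------

_HYDROPHILIC = {"R": 0.12, "K": 0.12, "D": 0.12, "E": 0.12, "N": 0.10,
                "Q": 0.10, "S": 0.12, "T": 0.10, "G": 0.10}
_HYDROPHOBIC = {"I": 0.18, "L": 0.18, "V": 0.16, "F": 0.12, "M": 0.08,
                "A": 0.16, "C": 0.06, "W": 0.06}
_ACIDIC = {"D": 0.25, "E": 0.25, "G": 0.15, "S": 0.15, "A": 0.10, "T": 0.10}
_BASIC = {"K": 0.25, "R": 0.25, "G": 0.15, "S": 0.15, "A": 0.10, "Q": 0.10}

#: Residue-frequency presets for sequence simulation. "bimodal-pI" is a
#: 50/50 mixture of acidic and basic compositions, giving a two-mode pI
#: distribution like the one seen in glue proteomes.
SEQUENCE_PRESETS: dict[str, object] = {
    "poly-I": {"I": 1.0},
    "hydrophilic": _HYDROPHILIC,
    "hydrophobic": _HYDROPHOBIC,
    "acidic": _ACIDIC,
    "basic": _BASIC,
    "uniform": {aa: 0.05 for aa in "ACDEFGHIKLMNPQRSTVWY"},
    "bimodal-pI": [_ACIDIC, _BASIC],
}

#: Silk gland types of a theridiid spider.
GLAND_TYPES = (
    "anterior_aggregate",
    "posterior_aggregate",
    "major_ampullate",
    "minor_ampullate",
    "flagelliform",
    "tubuliform",
    "pyriform",
)


def generate_protein_sequences(
    n: int,
    preset: str = "uniform",
    length_mean: int = 300,
    length_sd: int = 60,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Draw ``n`` (id, sequence) records from a residue-frequency preset.

    Mixture presets (a list of compositions) pick one component per
    sequence with equal probability. ``n = 0`` yields an empty list.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    comp = SEQUENCE_PRESETS.get(preset)
    if comp is None:
        raise ValueError(f"unknown preset {preset!r}; "
                         f"choose from {sorted(SEQUENCE_PRESETS)}")
    components = comp if isinstance(comp, list) else [comp]
    for c in components:
        if not c:
            raise ValueError("empty residue alphabet in preset")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        c = components[int(rng.integers(len(components)))]
        residues = list(c.keys())
        probs = np.asarray(list(c.values()), dtype=float)
        probs = probs / probs.sum()
        length = max(20, int(round(rng.normal(length_mean, length_sd))))
        seq = "".join(rng.choice(residues, size=length, p=probs))
        records.append((f"SYN{i:04d}", seq))
    return records


def generate_gland_tpm(
    protein_ids: list[str],
    aggregate_biased: list[str] | None = None,
    seed: int = 0,
    scale: float = 50.0,
) -> pd.DataFrame:
    """Simulate per-gland TPM vectors (transcripts x gland types).

    Proteins in ``aggregate_biased`` get most of their expression in the
    anterior aggregate gland; the rest are spread across gland types at
    random. Rows are non-negative and not all zero.
    """
    rng = np.random.default_rng(seed)
    biased = set(aggregate_biased or [])
    rows = []
    for pid in protein_ids:
        base = rng.gamma(shape=0.6, scale=scale, size=len(GLAND_TYPES))
        if pid in biased:
            base[0] += rng.gamma(shape=4.0, scale=10 * scale)
        rows.append(base)
    return pd.DataFrame(rows, index=pd.Index(protein_ids, name="transcript_id"),
                        columns=GLAND_TYPES)
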