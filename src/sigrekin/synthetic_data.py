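"""Synthetic-data generators with recorded ground truth.

Every input the analysis needs can be generated here, emulating the regimes of
the real study data: single-replicate log2 expression time courses on the
32-point 20-60 h fermentor grid with multiplicative (log-normal) noise,
GC-rich promoter sequences (the *S. coelicolor* genome is ~72% GC) with
bipartite sites planted at recorded positions, and flat gene-to-class
annotation tables with configurable class frequencies.

Reproducibility contract: every generator is a pure function of its
configuration and seed, and per-entity seeds are derived from the master seed
and an entity counter, so enlarging a cohort never perturbs the entities
already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ParameterError, StructuralError
from .expression_profiles import ExpressionProfile, Scale, TIME_GRID_HOURS
from .kinetic_model import KineticParams, integrate_model
from .motif_tools import (
    ALPHABET,
    CompositeMotif,
    PWM,
    build_composite_motif,
    consensus_pwm,
    gc_background,
)

#: Spacer-length frequencies observed for this sigma factor's binding sites
#: (59/21/11/9 out of 100 sites for 18/19/17/16 bp).
DEFAULT_SPACER_DISTRIBUTION: dict[int, float] = {16: 0.09, 17: 0.11, 18: 0.59, 19: 0.21}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study conditions.

    Defaults emulate the real data: the 32-point hour grid, log2 scale without
    replicates, additive Gaussian noise on the log2 scale (``noise_sd_log2``,
    a tunable — the source data's noise magnitude is not published), 72% GC
    background, 100 bp summit-window sequences, and the observed spacer-length
    distribution.
    """

    master_seed: int = 0
    time_grid: tuple[float, ...] = TIME_GRID_HOURS
    noise_sd_log2: float = 0.2
    gc_content: float = 0.72
    n_sequences: int = 100
    seq_length: int = 100
    spacer_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SPACER_DISTRIBUTION)
    )
    planting_rate: float = 0.9
    ode_dt: float = 0.05

    def __post_init__(self) -> None:
        grid = np.asarray(self.time_grid, dtype=float)
        if grid.size == 0 or (grid.size > 1 and not np.all(np.diff(grid) > 0)):
            raise ParameterError("time_grid must be non-empty and strictly increasing")
        if self.noise_sd_log2 < 0:
            raise ParameterError("noise_sd_log2 must be non-negative")
        if not (0 < self.gc_content < 1):
            raise ParameterError("gc_content must be in (0, 1)")
        if self.n_sequences < 1 or self.seq_length < 1:
            raise ParameterError("n_sequences and seq_length must be positive")
        if not (0 <= self.planting_rate <= 1):
            raise ParameterError("planting_rate must be in [0, 1]")
        if self.ode_dt <= 0:
            raise ParameterError("ode_dt must be positive")
        probs = dict(self.spacer_distribution)
        if any(p < 0 or p > 1 for p in probs.values()):
            raise ParameterError("spacer probabilities must be in [0, 1]")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ParameterError("spacer_distribution must sum to 1")
        object.__setattr__(self, "time_grid", tuple(float(t) for t in grid))
        object.__setattr__(self, "spacer_distribution", probs)

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.time_grid)

    @property
    def background(self) -> np.ndarray:
        return gc_background(self.gc_content)


@dataclass(frozen=True)
class TrueKinetics:
    params: KineticParams
    regulator_ids: tuple[str, ...]


@dataclass(frozen=True)
class PlantedSite:
    position: int
    strand: str
    spacer: int


@dataclass
class GroundTruth:
    """What was actually generated: true kinetics per gene, true site per
    sequence (None where no site was planted)."""

    genes: dict[str, TrueKinetics] = field(default_factory=dict)
    sites: dict[str, PlantedSite | None] = field(default_factory=dict)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        merged = GroundTruth(dict(self.genes), dict(self.sites))
        merged.genes.update(other.genes)
        merged.sites.update(other.sites)
        return merged

    @property
    def n_planted(self) -> int:
        return sum(1 for s in self.sites.values() if s is not None)


def entity_seed(seed: int, index: int) -> np.random.SeedSequence:
    """Per-entity seed: a pure function of (seed, entity counter)."""
    return np.random.SeedSequence([int(seed), int(index)])


# ---------------------------------------------------------------------------
# Expression time series
# ---------------------------------------------------------------------------

REGULATOR_SHAPES = ("pulse", "ramp", "biphasic")


def simulate_regulator_profile(
    config: SimulationConfig, shape: str, seed: int, gene_id: str | None = None
) -> ExpressionProfile:
    """A strictly positive regulator concentration profile on the config grid.

    Shapes (with seeded parameter jitter): ``pulse`` — a single Gaussian bump
    peaking strictly inside the grid; ``ramp`` — a sigmoidal rise; ``biphasic``
    — two bumps.  Linear scale; deterministic given the seed.
    """
    if shape not in REGULATOR_SHAPES:
        raise ParameterError(f"unknown shape {shape!r}; choose from {REGULATOR_SHAPES}")
    rng = np.random.default_rng(entity_seed(seed, 0))
    t = config.times
    s = (t - t[0]) / max(t[-1] - t[0], 1e-12)
    base = rng.uniform(0.2, 0.5)
    if shape == "pulse":
        center = rng.uniform(0.3, 0.7)
        width = rng.uniform(0.10, 0.18)
        amp = rng.uniform(2.0, 4.0)
        v = base + amp * np.exp(-0.5 * ((s - center) / width) ** 2)
    elif shape == "ramp":
        center = rng.uniform(0.4, 0.6)
        tau = rng.uniform(0.06, 0.12)
        amp = rng.uniform(2.0, 4.0)
        v = base + amp * expit((s - center) / tau)
    else:  # biphasic
        c1, c2 = rng.uniform(0.15, 0.3), rng.uniform(0.65, 0.85)
        w1, w2 = rng.uniform(0.06, 0.12), rng.uniform(0.06, 0.12)
        a1, a2 = rng.uniform(1.5, 3.0), rng.uniform(1.5, 3.0)
        v = (base + a1 * np.exp(-0.5 * ((s - c1) / w1) ** 2)
             + a2 * np.exp(-0.5 * ((s - c2) / w2) ** 2))
    return ExpressionProfile(gene_id or f"{shape}_regulator", t, v, Scale.LINEAR)


def simulate_target_expression(
    regulators: Sequence[ExpressionProfile],
    params: KineticParams,
    config: SimulationConfig,
    seed: int,
    gene_id: str = "gene",
) -> tuple[ExpressionProfile, GroundTruth]:
    """Forward-simulate a target gene and return its noisy log2 profile.

    The noiseless trajectory is the Euler solution of the kinetic model at
    step ``config.ode_dt`` sampled on the config grid; measurement noise is
    additive Gaussian on the log2 scale (log-normal multiplicative on linear
    reads).  With ``noise_sd_log2 == 0`` the de-logged output reproduces the
    integrator exactly.
    """
    for r in regulators:
        if len(r.times) != len(config.times) or not np.allclose(r.times, config.times):
            raise StructuralError(
                f"regulator {r.gene_id} is not on the configured time grid"
            )
    z = integrate_model(params, regulators, dt=config.ode_dt)
    values = np.maximum(z.values, 1e-12)
    log2_values = np.log2(values)
    if config.noise_sd_log2 > 0:
        rng = np.random.default_rng(entity_seed(seed, 0))
        log2_values = log2_values + config.noise_sd_log2 * rng.standard_normal(
            len(log2_values)
        )
    profile = ExpressionProfile(gene_id, config.times, log2_values, Scale.LOG2)
    truth = GroundTruth(
        genes={gene_id: TrueKinetics(params, tuple(r.gene_id for r in regulators))}
    )
    return profile, truth


def draw_gene_params(
    rng: np.random.Generator,
    regulators: Sequence[ExpressionProfile],
    weight_signs: Sequence[int],
    config: SimulationConfig,
) -> KineticParams:
    """Random but identifiable kinetic parameters for a synthetic gene.

    Weights have magnitude 1.5-4 with the requested signs (0 disconnects a
    regulator); the bias centers the sigmoid near its dynamic range at the
    regulators' mean level (a responsive promoter), degradation gives
    half-lives of roughly 0.5-2 h, and ``z0`` starts the gene at its steady
    state at the first time point.
    """
    if len(weight_signs) != len(regulators):
        raise ParameterError("one weight sign per regulator")
    w = []
    for sign in weight_signs:
        if sign == 0:
            w.append(0.0)
        else:
            w.append(float(np.sign(sign)) * rng.uniform(1.5, 4.0))
    w = tuple(w)
    y_means = np.array([float(np.mean(r.values)) for r in regulators])
    b = float(-(np.asarray(w) @ y_means) + rng.uniform(-1.0, 1.0))
    k2 = float(rng.uniform(0.3, 1.5))
    k1 = float(k2 * rng.uniform(4.0, 20.0))
    y0 = np.array([float(r.values[0]) for r in regulators])
    z0 = float(k1 * expit(np.asarray(w) @ y0 + b) / k2)
    return KineticParams(k1=k1, k2=k2, b=b, w=w, z0=z0)


def canonical_regulators(config: SimulationConfig) -> dict[str, ExpressionProfile]:
    """The cohort's two reference regulator profiles (deterministic).

    The ECF sigma factor is a mid-culture pulse; the housekeeping factor
    declines sigmoidally as the culture leaves exponential growth.  The two
    shapes are deliberately close to orthogonal over the grid (|r| < 0.15), so
    a dual-regulator decomposition into activator and repressor contributions
    is statistically identifiable — nearly mirror-image regulators would make
    the weight signs unrecoverable from a single noisy time course.
    """
    t = config.times
    s = (t - t[0]) / max(t[-1] - t[0], 1e-12)
    sigE_v = 0.3 + 3.0 * np.exp(-0.5 * ((s - 0.5) / 0.13) ** 2)
    hrdB_v = 0.4 + 3.0 * expit((0.55 - s) / 0.15)
    return {
        "sigE": ExpressionProfile("sigE", t, sigE_v, Scale.LINEAR),
        "hrdB": ExpressionProfile("hrdB", t, hrdB_v, Scale.LINEAR),
    }


def generate_cohort(
    config: SimulationConfig,
    n_sigE: int = 10,
    n_hrdB: int = 5,
    n_flat: int = 5,
    n_repressed: int = 0,
    seed: int | None = None,
) -> tuple[dict[str, ExpressionProfile], list[ExpressionProfile], GroundTruth]:
    """A labelled cohort: two regulators plus genes of the three study groups.

    Regulators come from :func:`canonical_regulators`.  Genes: ``n_sigE``
    activated by the ECF factor, ``n_repressed`` repressed by it, ``n_hrdB``
    activated by HrdB, ``n_flat`` with zero regulatory weight.  Returns the
    regulator profiles, the noisy log2 gene profiles, and the ground truth.
    """
    seed = config.master_seed if seed is None else seed
    regulators = canonical_regulators(config)

    spec = (
        [("sigE", +1)] * n_sigE
        + [("sigE", -1)] * n_repressed
        + [("hrdB", +1)] * n_hrdB
        + [("flat", 0)] * n_flat
    )
    profiles: list[ExpressionProfile] = []
    truth = GroundTruth()
    for i, (driver, sign) in enumerate(spec):
        rng = np.random.default_rng(entity_seed(seed, 1000 + i))
        reg = regulators["sigE" if driver == "flat" else driver]
        params = draw_gene_params(rng, [reg], [sign], config)
        gene_id = f"G{i:04d}_{driver}{'_rep' if sign < 0 else ''}"
        gene_seed = int(np.random.SeedSequence([seed, 2000 + i]).generate_state(1)[0]
                        % (2**31))
        profile, gt = simulate_target_expression(
            [reg], params, config, gene_seed, gene_id=gene_id
        )
        profiles.append(profile)
        truth = truth.merge(gt)
    return regulators, profiles, truth


# ---------------------------------------------------------------------------
# Promoter sequences
# ---------------------------------------------------------------------------

#: Synthetic half-site consensus sequences used for planted motifs: the -35
#: box follows the GGAACTT-like ECF consensus; the -10 box is an invented
#: GTCNNA-style core.  These stand in for discovered motifs in tests.
SYNTHETIC_CONSENSUS_35 = "GGAACTT"
SYNTHETIC_CONSENSUS_10 = "GTCTAA"


def default_composite_motifs(
    gc_content: float = 0.72,
    strength35: float = 0.8,
    strength10: float = 0.95,
    spacers: Sequence[int] = (16, 17, 18, 19),
) -> dict[int, CompositeMotif]:
    """A synthetic bipartite motif family, one composite per spacer length.

    The -10 element is the more conserved of the two halves, mirroring real
    sigma-factor promoters where the -10 box is discovered at far more sites
    than the -35 box.
    """
    bg = gc_background(gc_content)
    pwm35 = consensus_pwm(SYNTHETIC_CONSENSUS_35, strength35, bg, name="minus35")
    pwm10 = consensus_pwm(SYNTHETIC_CONSENSUS_10, strength10, bg, name="minus10")
    return {s: build_composite_motif(pwm35, pwm10, s) for s in spacers}


def _sample_site(
    motif: CompositeMotif, background: np.ndarray, rng: np.random.Generator,
    consensus_only: bool,
) -> dict[int, str]:
    """Motif-oriented bases for the informative columns of a composite."""
    probs = motif.probs(background)
    bases: dict[int, str] = {}
    for c in motif.informative_columns:
        if consensus_only:
            bases[int(c)] = ALPHABET[int(np.argmax(probs[c]))]
        else:
            bases[int(c)] = ALPHABET[rng.choice(4, p=probs[c] / probs[c].sum())]
    return bases


def generate_promoter_set(
    config: SimulationConfig,
    motifs: Mapping[int, CompositeMotif] | None = None,
    seed: int | None = None,
    consensus_sites: bool = False,
) -> tuple[dict[str, str], GroundTruth]:
    """GC-biased i.i.d. background sequences with ZOOPS-style planted sites.

    Each sequence independently receives a site with probability
    ``planting_rate``; the spacer length is drawn from the configured
    distribution, the strand and position uniformly, and the site bases from
    the composite's PWM columns (or the consensus with ``consensus_sites``).
    Ground truth records every planting.
    """
    seed = config.master_seed if seed is None else seed
    if motifs is None:
        motifs = default_composite_motifs(config.gc_content)
    for s in config.spacer_distribution:
        if config.spacer_distribution[s] > 0 and s not in motifs:
            raise ParameterError(f"no composite motif for spacer {s}")
    max_width = max(m.width for m in motifs.values())
    if config.seq_length < max_width:
        raise ParameterError(
            f"seq_length {config.seq_length} shorter than widest motif {max_width}"
        )
    bg = config.background
    spacer_keys = sorted(k for k, p in config.spacer_distribution.items() if p > 0)
    spacer_probs = np.array([config.spacer_distribution[k] for k in spacer_keys])
    spacer_probs = spacer_probs / spacer_probs.sum()

    seqs: dict[str, str] = {}
    truth = GroundTruth()
    for i in range(config.n_sequences):
        rng = np.random.default_rng(entity_seed(seed, i))
        chars = np.array(list(ALPHABET))[rng.choice(4, size=config.seq_length, p=bg)]
        sid = f"seq_{i:04d}"
        if rng.random() < config.planting_rate:
            spacer = int(spacer_keys[rng.choice(len(spacer_keys), p=spacer_probs)])
            motif = motifs[spacer]
            strand = "+" if rng.random() < 0.5 else "-"
            pos = int(rng.integers(0, config.seq_length - motif.width + 1))
            site = _sample_site(motif, bg, rng, consensus_sites)
            for c, base in site.items():
                if strand == "+":
                    chars[pos + c] = base
                else:
                    chars[pos + motif.width - 1 - c] = _COMP[base]
            truth.sites[sid] = PlantedSite(pos, strand, spacer)
        else:
            truth.sites[sid] = None
        seqs[sid] = "".join(chars)
    return seqs, truth


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def generate_annotation_table(
    n_genes: int,
    class_fractions: Mapping[str, float],
    seed: int = 0,
    gene_ids: Sequence[str] | None = None,
):
    """Assign each gene one class label with the given frequencies.

    Fractions must sum to at most 1; the remainder becomes ``unclassified``.
    Deterministic given the seed (per-gene derived seeds).
    """
    from .enrichment_stats import UNCLASSIFIED, AnnotationTable

    if n_genes < 0:
        raise ParameterError("n_genes must be non-negative")
    for cls, f in class_fractions.items():
        if f < 0:
            raise ParameterError(f"negative fraction for class {cls!r}")
    total = sum(class_fractions.values())
    if total > 1 + 1e-9:
        raise ParameterError("class fractions must sum to at most 1")
    classes = list(class_fractions) + [UNCLASSIFIED]
    cum = np.cumsum([class_fractions[c] for c in class_fractions] + [max(1 - total, 0)])
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ParameterError("gene_ids length must equal n_genes")
    labels = {}
    for i, gid in enumerate(gene_ids):
        u = np.random.default_rng(entity_seed(seed, i)).random()
        labels[gid] = classes[int(np.searchsorted(cum, u, side="right"))]
    return AnnotationTable(labels)


# ---------------------------------------------------------------------------
# Ground-truth I/O
# ---------------------------------------------------------------------------

def write_ground_truth_tsv(truth: GroundTruth, gene_path=None, site_path=None) -> None:
    if gene_path is not None:
        rows = []
        for gid, tk in sorted(truth.genes.items()):
            row = {
                "gene_id": gid, "k1": tk.params.k1, "k2": tk.params.k2,
                "b": tk.params.b, "z0": tk.params.z0,
                "regulators": ",".join(tk.regulator_ids),
            }
            for j, wj in enumerate(tk.params.w):
                row[f"w{j + 1}"] = wj
            rows.append(row)
        pd.DataFrame(rows).to_csv(gene_path, sep="\t", index=False)
    if site_path is not None:
        rows = []
        for sid, site in sorted(truth.sites.items()):
            if site is None:
                rows.append({"seq_id": sid, "position": -1, "strand": ".",
                             "spacer": -1})
            else:
                rows.append({"seq_id": sid, "position": site.position,
                             "strand": site.strand, "spacer": site.spacer})
        pd.DataFrame(rows).to_csv(site_path, sep="\t", index=False)
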