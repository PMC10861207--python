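"""Synthetic cohorts, trajectories, promoters and DE tables.

Every pipeline stage has a paired generator here so the whole analysis
is testable without assay data.  The generators emulate the statistical
structure the pipeline assumes — exponential or Gompertz mortality with
an accelerated hazard under stress, two-state (motile/paralyzed)
centroid tracks with Poisson reversal events, uniform-background
promoters with planted consensus sites, and DE tables mixing true
effects with nulls — and return the ground truth alongside the data so
recovery can be asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .locomotion import Track
from .regulatory import SKN1_MOTIFS, DegRecord, PromoterSeq
from .survival import EventTable

__all__ = [
    "CohortSpec",
    "TrackSpec",
    "RegulatorySpec",
    "simulate_cohort",
    "simulate_tracks",
    "generate_regulatory",
]


@dataclass(frozen=True)
class CohortSpec:
    """One simulated survival cohort.

    ``model`` is "exponential" (constant hazard ``rate``) or "gompertz"
    (hazard h(t) = a * exp(b t), the conventional ageing form).  Deaths
    beyond ``max_follow_up`` are censored at the horizon.
    """

    group: str = "cohort"
    model: str = "exponential"
    rate: float = 0.1          # exponential hazard (1/time unit)
    gompertz_a: float = 0.01   # baseline hazard
    gompertz_b: float = 0.1    # hazard doubling exponent (1/time unit)
    n: int = 100
    max_follow_up: float | None = None
    time_unit: str = "days"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if self.model == "exponential":
            if self.rate <= 0:
                raise ValueError("exponential rate must be positive")
        elif self.model == "gompertz":
            if self.gompertz_a <= 0 or self.gompertz_b < 0:
                raise ValueError("gompertz requires a > 0 and b >= 0")
        else:
            raise ValueError(f"unknown survival model {self.model!r}")


@dataclass(frozen=True)
class TrackSpec:
    """Two-state worm-trajectory generator settings.

    Motile worms follow a correlated random walk (wrapped-normal heading
    increments) with Poisson reversal events at ``reversal_rate``;
    paralyzed worms jitter at ``paralyzed_speed_mean``, well below the
    0.015 mm/s paralysis speed threshold.
    """

    n_worms: int = 30
    duration: float = 30.0          # s, matches a 30-s tracking video
    fps: float = 10.0
    motile_speed_mean: float = 0.12  # mm/s
    motile_speed_sd: float = 0.03
    paralyzed_speed_mean: float = 0.002  # mm/s, << 0.015
    reversal_rate: float = 0.2      # events/s
    paralyzed_fraction: float = 0.0
    heading_sd: float = 0.3         # rad per step, heading persistence

    def __post_init__(self):
        if not 0 <= self.paralyzed_fraction <= 1:
            raise ValueError("paralyzed_fraction must lie in [0, 1]")
        if self.fps <= 0 or self.duration <= 0:
            raise ValueError("fps and duration must be positive")
        if min(self.motile_speed_mean, self.paralyzed_speed_mean) < 0:
            raise ValueError("speeds must be nonnegative")


@dataclass(frozen=True)
class RegulatorySpec:
    """Promoter + DE-table generator settings.

    A ``planted_fraction`` of genes receive ``sites_per_planted`` motif
    copies at non-overlapping uniform positions and strands; a
    ``de_fraction`` of genes carry true effects (|log2FC| >= 1 by
    construction, small FDR) while nulls get log2FC near 0 and FDR ~
    Uniform(0, 1).
    """

    n_genes: int = 100
    promoter_length: int = 1500
    gc_content: float = 0.36   # C. elegans-like genomic GC
    planted_fraction: float = 0.3
    sites_per_planted: int = 1
    motifs: tuple = SKN1_MOTIFS
    de_fraction: float = 0.3
    effect_log2fc_mean: float = 2.0
    effect_log2fc_sd: float = 0.5
    true_fdr_max: float = 0.01
    null_log2fc_sd: float = 0.3

    def __post_init__(self):
        for name in ("planted_fraction", "de_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.promoter_length < max(len(m) for m in self.motifs):
            raise ValueError("promoter_length shorter than motif length")


def simulate_cohort(spec: CohortSpec, seed: int) -> EventTable:
    """Draw death times from the specified law; censor at the horizon."""
    rng = np.random.default_rng(seed)
    if spec.model == "exponential":
        times = rng.exponential(1.0 / spec.rate, size=spec.n)
    else:
        # inverse-CDF for Gompertz hazard a*exp(b*t); b = 0 degenerates
        # to exponential(a)
        u = rng.uniform(size=spec.n)
        if spec.gompertz_b == 0:
            times = -np.log(u) / spec.gompertz_a
        else:
            times = np.log1p(-spec.gompertz_b * np.log(u) / spec.gompertz_a) / spec.gompertz_b
    event = np.ones(spec.n, dtype=int)
    if spec.max_follow_up is not None:
        censored = times > spec.max_follow_up
        times = np.where(censored, spec.max_follow_up, times)
        event = np.where(censored, 0, 1)
    ids = np.array([f"{spec.group}_{i:05d}" for i in range(spec.n)], dtype=object)
    return EventTable(ids, np.full(spec.n, spec.group, dtype=object),
                      times, event, spec.time_unit)


def simulate_tracks(spec: TrackSpec, seed: int) -> tuple[list[Track], pd.DataFrame]:
    """Generate per-worm tracks plus a truth table.

    Truth columns: worm_id, paralyzed (generator state), n_reversals
    (Poisson reversal events actually inserted).
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(spec.duration * spec.fps)) + 1
    dt = 1.0 / spec.fps
    t = np.arange(n_frames) * dt

    n_par = int(round(spec.paralyzed_fraction * spec.n_worms))
    states = np.array([True] * n_par + [False] * (spec.n_worms - n_par))
    rng.shuffle(states)

    tracks, truth_rows = [], []
    for w in range(spec.n_worms):
        wid = f"worm_{w:04d}"
        paralyzed = bool(states[w])
        if paralyzed:
            # isotropic jitter: step length ~ |N(0, sigma)| with mean
            # paralyzed_speed_mean * dt
            sigma = spec.paralyzed_speed_mean * dt * np.sqrt(np.pi / 2)
            steps = rng.normal(0.0, sigma, size=(n_frames - 1, 2))
            xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
            n_rev = 0
        else:
            heading = rng.uniform(0, 2 * np.pi)
            reversal = rng.uniform(size=n_frames - 1) < spec.reversal_rate * dt
            n_rev = int(reversal.sum())
            x, y = [0.0], [0.0]
            for i in range(n_frames - 1):
                if reversal[i]:
                    heading += np.pi + rng.normal(0.0, 0.05)
                else:
                    heading += rng.normal(0.0, spec.heading_sd)
                speed = max(rng.normal(spec.motile_speed_mean, spec.motile_speed_sd), 0.0)
                x.append(x[-1] + speed * dt * np.cos(heading))
                y.append(y[-1] + speed * dt * np.sin(heading))
            xy = np.column_stack([x, y])
        tracks.append(Track(wid, t, xy[:, 0], xy[:, 1], fps=spec.fps))
        truth_rows.append({"worm_id": wid, "paralyzed": paralyzed, "n_reversals": n_rev})
    return tracks, pd.DataFrame(truth_rows)


def generate_regulatory(
    spec: RegulatorySpec, seed: int
) -> tuple[list[PromoterSeq], list[DegRecord], pd.DataFrame]:
    """Generate promoters, a DE table, and the ground truth.

    Truth columns: gene_id, planted (site carrier), n_planted_sites,
    true_de (carries a real effect).
    """
    rng = np.random.default_rng(seed)
    gc = spec.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGT"))

    gene_ids = [f"gene_{i:05d}" for i in range(spec.n_genes)]
    n_planted = int(round(spec.planted_fraction * spec.n_genes))
    planted = np.zeros(spec.n_genes, dtype=bool)
    planted[rng.choice(spec.n_genes, size=n_planted, replace=False)] = True

    from Bio.Seq import Seq as _Seq

    promoters = []
    for gi, gid in enumerate(gene_ids):
        seq = "".join(rng.choice(alphabet, size=spec.promoter_length, p=probs))
        if planted[gi]:
            seq = _plant_sites(seq, spec, rng, _Seq)
        promoters.append(PromoterSeq(gene_id=gid, seq=seq, source="provided_fasta"))

    n_de = int(round(spec.de_fraction * spec.n_genes))
    true_de = np.zeros(spec.n_genes, dtype=bool)
    true_de[rng.choice(spec.n_genes, size=n_de, replace=False)] = True

    degs = []
    for gi, gid in enumerate(gene_ids):
        if true_de[gi]:
            mag = max(rng.normal(spec.effect_log2fc_mean, spec.effect_log2fc_sd), 1.0)
            lfc = mag * rng.choice([-1.0, 1.0])
            fdr = rng.uniform(0.0, spec.true_fdr_max)
        else:
            lfc = rng.normal(0.0, spec.null_log2fc_sd)
            fdr = rng.uniform(0.0, 1.0)
        degs.append(DegRecord(gene_id=gid, log2fc=float(lfc), fdr=float(fdr)))

    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "planted": planted,
        "n_planted_sites": np.where(planted, spec.sites_per_planted, 0),
        "true_de": true_de,
    })
    return promoters, degs, truth


def _plant_sites(seq: str, spec: RegulatorySpec, rng, _Seq) -> str:
    """Insert sites_per_planted concrete motif words at non-overlapping
    uniform positions/strands."""
    L = len(seq)
    occupied: list[tuple[int, int]] = []
    chars = list(seq)
    max_len = max(len(m) for m in spec.motifs)
    if spec.sites_per_planted * (2 * max_len) > L:
        raise ValueError("too many sites to place without overlap")
    placed = 0
    attempts = 0
    while placed < spec.sites_per_planted:
        attempts += 1
        if attempts > 1000:
            raise ValueError("too many sites to place without overlap")
        motif = spec.motifs[rng.integers(len(spec.motifs))]
        word = sorted(motif.expansion)[rng.integers(len(motif.expansion))]
        if rng.random() < 0.5:
            word = str(_Seq(word).reverse_complement())
        start = int(rng.integers(0, L - len(word) + 1))
        span = (start, start + len(word))
        if any(span[0] < e and s < span[1] for s, e in occupied):
            continue
        chars[span[0]:span[1]] = list(word)
        occupied.append(span)
        placed += 1
    return "".join(chars)
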