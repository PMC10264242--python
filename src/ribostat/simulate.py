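"""Synthetic ribosome-profiling and 3'-end count data with known truth.

The generator emulates the data model the statistical tests assume:

* RNA counts per transcript and sample are negative binomial with a
  log-normal baseline expression, per-sample depth factors and dispersion
  phi (variance mu + phi mu^2);
* RPF counts share the transcript's expression scaled by a per-transcript
  TE odds, times exp(logTER) in the second group for effect transcripts;
* codon profiles distribute a transcript's RPF total uniformly over its
  codons, with optional multiplicative stalling peaks (the spiked total is
  inflated by (L + (fold-1) m) / L for m spiked codons so matrix and
  profile views stay consistent);
* poly(A)-site usage per transcript is a symmetric-Dirichlet multinomial;
  shifted transcripts add delta to the proximal site's log-odds in
  condition 2.

All sampling flows through one numpy Generator seeded explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    CodonProfileSet,
    CountMatrix,
    DataError,
    DesignMatrix,
    PasCountTable,
    ReadType,
)


@dataclass
class RiboSimParams:
    """Study conditions for the paired RPF/RNA generator.

    Defaults describe a two-group (3 vs 3) bulk experiment with mean
    RNA depth ~200 reads per transcript, NB dispersion 0.1, 10% of
    transcripts carrying logTER = ln 2, and x10 stalling peaks at 5 codons
    when a stalling fraction is requested.
    """

    n_transcripts: int = 2000
    codon_length: int = 150
    samples_per_group: int = 3
    n_groups: int = 2
    mean_expression: float = 200.0     # log-normal median of NB means
    sd_log_expression: float = 0.7
    dispersion: float = 0.1            # phi in var = mu + phi mu^2
    baseline_te_odds: float = 1.0      # median RPF:RNA odds
    sd_log_te: float = 0.3
    effect_fraction: float = 0.1
    effect_logter: float = float(np.log(2.0))
    stall_fraction: float = 0.0        # fraction of transcripts with peaks
    stall_codons: int = 5
    stall_fold: float = 10.0
    depth_sd_log: float = 0.2          # per-sample library depth spread
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts < 1 or self.codon_length < 2:
            raise DataError("need >= 1 transcript and >= 2 codons")
        if not (0 <= self.effect_fraction <= 1 and 0 <= self.stall_fraction <= 1):
            raise DataError("fractions must lie in [0, 1]")
        if min(self.mean_expression, self.dispersion, self.baseline_te_odds,
               self.stall_fold) <= 0:
            raise DataError("rates and folds must be positive")


@dataclass
class ApaSimParams:
    """Study conditions for the poly(A)-site generator: 2-4 sites per
    transcript, symmetric Dirichlet(2) baseline usage, 500 reads per site,
    3 samples per condition, 10% of transcripts with a +1.0 proximal
    log-odds shift in condition 2."""

    n_transcripts: int = 1000
    min_sites: int = 2
    max_sites: int = 4
    dirichlet_conc: float = 2.0
    reads_per_site: float = 500.0
    samples_per_condition: int = 3
    shift_fraction: float = 0.1
    shift_delta: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not 2 <= self.min_sites <= self.max_sites:
            raise DataError("need 2 <= min_sites <= max_sites")
        if self.reads_per_site <= 0 or self.dirichlet_conc <= 0:
            raise DataError("reads_per_site and dirichlet_conc must be positive")
        if not 0 <= self.shift_fraction <= 1:
            raise DataError("shift_fraction must lie in [0, 1]")


def _nb(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB draws with variance mu + phi mu^2 (gamma-Poisson mixture)."""
    mean = np.clip(mean, 1e-12, None)
    shape = 1.0 / phi
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam).astype(float)


def simulate_ribo(
    params: RiboSimParams,
) -> tuple[CountMatrix, CountMatrix, CodonProfileSet, pd.DataFrame, DesignMatrix]:
    """Generate (rna, rpf, codon profiles, ground truth, design)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    J, L = params.n_transcripts, params.codon_length
    n_samples = params.samples_per_group * params.n_groups
    tx_ids = [f"tx{j:05d}" for j in range(J)]
    groups = np.repeat(np.arange(params.n_groups), params.samples_per_group)
    sample_ids = [f"g{g}_r{r}" for g in range(params.n_groups)
                  for r in range(params.samples_per_group)]

    mu = params.mean_expression * np.exp(
        rng.normal(0.0, params.sd_log_expression, J)
    )
    te_odds = params.baseline_te_odds * np.exp(rng.normal(0.0, params.sd_log_te, J))
    depth_rna = np.exp(rng.normal(0.0, params.depth_sd_log, n_samples))
    depth_rpf = np.exp(rng.normal(0.0, params.depth_sd_log, n_samples))

    effect = rng.random(J) < params.effect_fraction
    logter = np.where(effect, params.effect_logter, 0.0)
    stalled = rng.random(J) < params.stall_fraction
    spiked_codons = {}
    for j in np.flatnonzero(stalled):
        spiked_codons[j] = np.sort(
            rng.choice(L, size=min(params.stall_codons, L), replace=False)
        )

    # RPF and RNA libraries come from the same biological sample, so the
    # overdispersed expression level is a shared latent: both assays are
    # Poisson reads of one gamma-distributed abundance. Marginals stay
    # NB(mu*depth, phi); the within-sample RPF:RNA odds carries only
    # sampling noise, which is what the TE odds model describes.
    shape = 1.0 / params.dispersion
    expression = rng.gamma(shape, (mu / shape)[:, None], size=(J, n_samples))
    rna = rng.poisson(expression * depth_rna[None, :]).astype(float)

    group_mult = np.exp(logter[:, None] * (groups[None, :] > 0))
    rpf_mean = expression * depth_rpf[None, :] * te_odds[:, None] * group_mult
    stall_scale = np.ones(J)
    for j, codons in spiked_codons.items():
        m = len(codons)
        stall_scale[j] = (L + (params.stall_fold - 1.0) * m) / L
    rpf = rng.poisson(rpf_mean * stall_scale[:, None]).astype(float)

    profiles = {}
    for j in range(J):
        w = np.ones(L)
        if j in spiked_codons:
            w[spiked_codons[j]] = params.stall_fold
        w = w / w.sum()
        mat = np.column_stack(
            [rng.multinomial(int(rpf[j, k]), w) for k in range(n_samples)]
        ).astype(float)
        profiles[tx_ids[j]] = pd.DataFrame(mat, columns=sample_ids)

    rna_cm = CountMatrix(pd.DataFrame(rna, index=tx_ids, columns=sample_ids), ReadType.RNA)
    rpf_cm = CountMatrix(pd.DataFrame(rpf, index=tx_ids, columns=sample_ids), ReadType.RPF)
    truth = pd.DataFrame(
        {
            "transcript_id": tx_ids,
            "true_logTER": logter,
            "is_effect": effect,
            "is_stalled": stalled,
            "spiked_codons": [
                ",".join(map(str, spiked_codons.get(j, []))) for j in range(J)
            ],
            "mean_expression": mu,
            "te_odds": te_odds,
        }
    ).set_index("transcript_id")
    design = DesignMatrix(
        pd.DataFrame({"group": (groups > 0).astype(float)}, index=sample_ids)
    )
    return rna_cm, rpf_cm, CodonProfileSet(profiles), truth, design


def simulate_apa(params: ApaSimParams) -> tuple[PasCountTable, pd.DataFrame, DesignMatrix]:
    """Generate (pas table, ground truth, design) for two conditions."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    J = params.n_transcripts
    n_per = params.samples_per_condition
    sample_ids = [f"c{c}_r{r}" for c in range(2) for r in range(n_per)]
    cond = np.repeat([0, 1], n_per)

    shifted = rng.random(J) < params.shift_fraction
    rows = []
    ranks = {}
    truth_rows = []
    for j in range(J):
        tx = f"tx{j:05d}"
        S = int(rng.integers(params.min_sites, params.max_sites + 1))
        usage = rng.dirichlet(np.full(S, params.dirichlet_conc))
        delta = params.shift_delta if shifted[j] else 0.0
        # condition-2 usage: add delta to the proximal (rank-1) log-odds
        logits = np.log(np.clip(usage, 1e-12, None))
        logits2 = logits.copy()
        logits2[0] += delta
        usage2 = np.exp(logits2 - logits2.max())
        usage2 = usage2 / usage2.sum()
        total = params.reads_per_site * S
        counts = np.column_stack(
            [
                rng.multinomial(int(total), usage if cond[k] == 0 else usage2)
                for k in range(2 * n_per)
            ]
        ).astype(float)
        for s in range(S):
            site = f"pA{s + 1}"
            rows.append((tx, site, *counts[s]))
            ranks[(tx, site)] = s + 1
        truth_rows.append(
            {
                "transcript_id": tx,
                "n_sites": S,
                "true_delta": delta,
                "is_shifted": bool(shifted[j]),
                "baseline_proximal_usage": usage[0],
            }
        )
    df = pd.DataFrame(rows, columns=["transcript_id", "site_id", *sample_ids])
    df = df.set_index(["transcript_id", "site_id"])
    rank_s = pd.Series(ranks)
    rank_s.index.names = ["transcript_id", "site_id"]
    pas = PasCountTable(df.astype(float), rank_s, rank_source="simulated")
    truth = pd.DataFrame(truth_rows).set_index("transcript_id")
    design = DesignMatrix(
        pd.DataFrame({"condition": cond.astype(float)}, index=sample_ids)
    )
    return pas, truth, design
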