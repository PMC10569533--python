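"""Ground-truthed synthetic cohorts with the structure the analysis assumes.

The generator produces everything the pipeline consumes — a chromatin-state
segmentation, FIMO-style motif occurrences, per-donor mutation records for
one or more cancer types — together with the latent ground truth, so every
downstream stage (model fidelity, attribution, excess-region detection,
donor classification) can be scored against known answers.

Generative model
----------------
* Regions: lengths log-uniform on [1 kb, 100 kb], tiled contiguously over a
  handful of synthetic chromosomes; each region gets a hidden *context*
  (an epigenetic regime) and a chromatin-state label whose distribution
  depends on the context.
* Features: zero-inflated motif scores.  Each context has a block of marker
  motifs that occur frequently in its regions; background motifs occur
  rarely.  Nonzero scores are 5 + Gamma(2, 1) — the -log10 p-value of a
  retained occurrence is at least 5 because of the FIMO cutoff of 1e-5.
  Marker blocks make the context identifiable from the features; without
  them a locally linear rate model would be unlearnable from X.
* Rates: each context c carries a sparse coefficient vector beta_c; the
  latent response is beta_c . x standardized across regions plus Gaussian
  noise, then pushed through the inverse density transforms
  (z -> log2-density -> density -> expected count lambda_i given region
  length and cohort depth).  A spiked fraction of regions ("cancer-related",
  each owned by one cancer type) has lambda multiplied by a factor >= 1 in
  that type only.  Observed counts are Poisson(lambda).
* Records: counts are materialised as point mutations at uniform positions
  within the region and attributed to donors multinomially with symmetric
  probabilities.

All randomness flows from one integer seed; outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import io_formats
from .featurize import FeatureMatrix

#: the core-15 chromatin-state mnemonics used for synthetic state labels
CHROMHMM_STATES = ["TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh",
                   "ZNF/Rpts", "Het", "TssBiv", "BivFlnk", "EnhBiv",
                   "ReprPC", "ReprPCWk", "Quies"]

BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``total_mutation_target`` is the approximate cohort total *per cancer
    type*; with the defaults the mean expected count per region is ~100,
    emulating a deeply sampled merged cohort in which region-level counts
    are informative.
    """

    n_regions: int = 5000
    p_motifs: int = 100
    n_contexts: int = 4
    coef_sparsity: float = 0.1        # fraction of nonzero coefficients per context
    feature_zero_prob: float = 0.85   # zero-inflation for background motifs
    marker_zero_prob: float = 0.2     # zero-inflation for a context's marker motifs
    feature_scale: float = 1.0        # scale of nonzero coefficient magnitudes
    noise_sd: float = 0.1             # latent Gaussian noise, z-scale units
    density_log2_sd: float = 1.0      # spread of log2 density across regions
    spike_fraction: float = 0.0
    spike_multiplier: float = 1.0
    n_types: int = 1
    donors_per_type: int = 40
    total_mutation_target: int = 500_000
    n_chromosomes: int = 8
    region_length_range: tuple[int, int] = (1000, 100_000)
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.spike_fraction < 1):
            raise ValueError("spike_fraction must be in [0, 1)")
        if self.spike_multiplier < 1:
            raise ValueError("spike_multiplier must be >= 1")
        for name in ("n_regions", "p_motifs", "n_contexts", "n_types",
                     "donors_per_type", "total_mutation_target"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.total_mutation_target / self.n_regions < 1:
            raise ValueError("infeasible config: expected counts below 1 per region "
                             "(raise total_mutation_target or lower n_regions)")


@dataclass
class GroundTruth:
    """Latent state of a simulated cohort."""

    context_of_region: np.ndarray     # (n,)
    beta_by_context: np.ndarray       # (n_contexts, p)
    latent_linear: np.ndarray         # (n,) standardized beta_c . x
    latent: np.ndarray                # latent_linear + Gaussian noise
    base_lambda: np.ndarray           # (n,) expected counts before spiking
    lambda_by_type: np.ndarray        # (n_types, n)
    spiked: np.ndarray                # (n,) bool
    spike_owner: np.ndarray           # (n,) owning type index, -1 if unspiked
    counts_by_type: np.ndarray        # (n_types, n) Poisson draws
    d1_mean: float                    # offset used to map latent -> log2 density
    d1_sd: float


@dataclass
class Cohort:
    config: SimulationConfig
    segmentation: pd.DataFrame
    mutations: pd.DataFrame           # all types pooled; tumor_type column
    occurrences: pd.DataFrame         # FIMO-style
    features: FeatureMatrix
    truth: GroundTruth

    @property
    def totals_by_type(self) -> np.ndarray:
        return self.truth.counts_by_type.sum(axis=1)


def simulate_null_counts(lam, seed: int = 0) -> np.ndarray:
    """Independent Poisson draws with the given expectations."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("lambda must be nonnegative")
    return np.random.default_rng(seed).poisson(lam)


def _solve_density_offset(latent: np.ndarray, lengths: np.ndarray,
                          d1_sd: float) -> float:
    """Find mu such that sum_i D_i * l_i/1000 == 1e6 with
    D_i = 2^(latent_i * d1_sd + mu) - 1 clamped at 0.

    That normalisation makes sum(lambda_i) == T for any cohort depth T,
    because lambda_i = D_i * (l_i/1000) * (T/1e6).
    """
    lk = lengths / 1000.0

    def gap(mu):
        D = np.maximum(np.exp2(latent * d1_sd + mu) - 1.0, 0.0)
        return float(np.sum(D * lk)) - 1e6

    return brentq(gap, -30.0, 40.0, xtol=1e-12)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate one cohort; see the module docstring for the model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p, K = config.n_regions, config.p_motifs, config.n_contexts

    # -- regions ------------------------------------------------------------
    lo, hi = config.region_length_range
    lengths = np.floor(np.exp2(rng.uniform(np.log2(lo), np.log2(hi), size=n))).astype(np.int64)
    chrom_of = np.minimum(np.arange(n) * config.n_chromosomes // n,
                          config.n_chromosomes - 1)
    starts = np.zeros(n, dtype=np.int64)
    for c in range(config.n_chromosomes):
        idx = np.flatnonzero(chrom_of == c)
        starts[idx] = np.concatenate([[0], np.cumsum(lengths[idx])[:-1]])
    context = rng.integers(0, K, size=n)

    # chromatin-state labels correlated with the hidden context
    state_group = np.array_split(np.arange(len(CHROMHMM_STATES)), K)
    states = np.empty(n, dtype=object)
    for c in range(K):
        idx = np.flatnonzero(context == c)
        own = state_group[c % len(state_group)]
        pick_own = rng.random(len(idx)) < 0.7
        states[idx] = np.where(
            pick_own,
            np.array(CHROMHMM_STATES)[rng.choice(own, size=len(idx))],
            np.array(CHROMHMM_STATES)[rng.integers(0, len(CHROMHMM_STATES), size=len(idx))])

    segmentation = pd.DataFrame({
        "region_id": np.arange(n),
        "chrom": [f"chr{c + 1}" for c in chrom_of],
        "start": starts,
        "end": starts + lengths,
        "state": states,
    })
    segmentation["length_bp"] = lengths

    # -- features: zero-inflated marker-block scores ------------------------
    block = max(1, p // (2 * K))
    present_prob = np.full((K, p), 1.0 - config.feature_zero_prob)
    for c in range(K):
        present_prob[c, c * block:(c + 1) * block] = 1.0 - config.marker_zero_prob
    present = rng.random((n, p)) < present_prob[context]
    X = np.where(present, 5.0 + rng.gamma(2.0, 1.0, size=(n, p)), 0.0)

    # -- sparse per-context coefficients ------------------------------------
    # Each beta_c is centered against the context's expected feature vector
    # (restricted to its support), making the latent mean-zero by
    # construction: the prediction head has no intercept, so a mean-zero
    # latent keeps the truth exactly inside the representable model family.
    k_nonzero = max(1, round(config.coef_sparsity * p))
    mean_feature = present_prob * 7.0  # E[nonzero score] = 5 + shape*scale = 7
    beta = np.zeros((K, p))
    for c in range(K):
        own = np.arange(c * block, min((c + 1) * block, p))
        n_own = min(k_nonzero // 2, len(own))
        chosen = list(rng.choice(own, size=n_own, replace=False))
        others = np.setdiff1d(np.arange(p), chosen)
        chosen += list(rng.choice(others, size=k_nonzero - n_own, replace=False))
        support = np.array(chosen)
        values = rng.normal(0.0, 1.0, size=k_nonzero) * config.feature_scale
        if k_nonzero >= 2:   # a single coefficient cannot be centered away
            m_s = mean_feature[c, support]
            values -= (values @ m_s) / (m_s @ m_s) * m_s
        beta[c, support] = values

    linear = np.einsum("ij,ij->i", X, beta[context])
    if linear.std() == 0:
        raise ValueError("degenerate latent response (constant); "
                         "increase p_motifs or coef_sparsity")
    z_linear = linear / linear.std()   # scale only; mean is ~0 by design
    latent = z_linear + rng.normal(0.0, config.noise_sd, size=n)

    # -- invert the density transforms to expected counts -------------------
    T = config.total_mutation_target
    mu = _solve_density_offset(latent, lengths.astype(float), config.density_log2_sd)
    D = np.maximum(np.exp2(latent * config.density_log2_sd + mu) - 1.0, 0.0)
    base_lambda = D * (lengths / 1000.0) * (T / 1e6)
    if base_lambda.max() < 1:
        raise ValueError("infeasible config: all expected counts < 1")

    # -- spiked (cancer-related) regions, each owned by one type ------------
    n_spiked = int(round(config.spike_fraction * n))
    spiked = np.zeros(n, dtype=bool)
    spike_owner = np.full(n, -1, dtype=np.int64)
    if n_spiked:
        which = rng.choice(n, size=n_spiked, replace=False)
        spiked[which] = True
        spike_owner[which] = np.arange(n_spiked) % config.n_types
    lambda_by_type = np.tile(base_lambda, (config.n_types, 1))
    for t in range(config.n_types):
        mask = spike_owner == t
        lambda_by_type[t, mask] *= config.spike_multiplier

    counts_by_type = rng.poisson(lambda_by_type)

    # -- materialise mutation records ---------------------------------------
    frames = []
    for t in range(config.n_types):
        counts = counts_by_type[t]
        region_idx = np.repeat(np.arange(n), counts)
        total = len(region_idx)
        offs = rng.random(total) * lengths[region_idx]
        pos = starts[region_idx] + offs.astype(np.int64) + 1  # 1-based in (start, end]
        ref = rng.integers(0, 4, size=total)
        alt = (ref + rng.integers(1, 4, size=total)) % 4
        donor = rng.integers(0, config.donors_per_type, size=total)
        frames.append(pd.DataFrame({
            "chrom": segmentation["chrom"].to_numpy()[region_idx],
            "pos": pos,
            "ref": BASES[ref],
            "alt": BASES[alt],
            "donor_id": [f"t{t}_d{d}" for d in donor],
            "tumor_type": f"type{t}",
        }))
    mutations = pd.concat(frames, ignore_index=True)

    # -- FIMO-style occurrences consistent with X ----------------------------
    rows, cols = np.nonzero(X)
    width = 10
    mid0 = starts[rows] + lengths[rows] // 2
    occ_start = np.maximum(mid0 - width // 2 + 1, starts[rows] + 1)
    occurrences = pd.DataFrame({
        "motif_id": [f"M{j:04d}" for j in cols],
        "chrom": segmentation["chrom"].to_numpy()[rows],
        "start": occ_start,
        "stop": occ_start + width - 1,
        "strand": "+",
        "score": X[rows, cols],
        "p_value": np.power(10.0, -X[rows, cols]),
    })

    features = FeatureMatrix(values=X, region_ids=np.arange(n),
                             motif_ids=[f"M{j:04d}" for j in range(p)])
    truth = GroundTruth(context_of_region=context, beta_by_context=beta,
                        latent_linear=z_linear, latent=latent,
                        base_lambda=base_lambda, lambda_by_type=lambda_by_type,
                        spiked=spiked, spike_owner=spike_owner,
                        counts_by_type=counts_by_type,
                        d1_mean=mu, d1_sd=config.density_log2_sd)
    return Cohort(config=config, segmentation=segmentation, mutations=mutations,
                  occurrences=occurrences, features=features, truth=truth)


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir) -> None:
    """Write the cohort as the plain-text files the CLI pipeline reads."""
    import yaml

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io_formats.write_segmentation(cohort.segmentation, out / "segmentation.bed")
    io_formats.write_mutations(cohort.mutations, out / "mutations.tsv")
    io_formats.write_fimo(cohort.occurrences, out / "fimo.tsv")

    tr = cohort.truth
    truth_df = pd.DataFrame({
        "region_id": np.arange(len(tr.context_of_region)),
        "context": tr.context_of_region,
        "spiked": tr.spiked.astype(int),
        "spike_owner": tr.spike_owner,
        "latent_linear": tr.latent_linear,
        "latent": tr.latent,
        "base_lambda": tr.base_lambda,
    })
    truth_df.to_csv(out / "ground_truth.tsv", sep="\t", index=False, float_format="%.17g")
    beta_df = pd.DataFrame(tr.beta_by_context, columns=cohort.features.motif_ids)
    beta_df.to_csv(out / "beta_by_context.tsv", sep="\t", index=False, float_format="%.17g")

    cfg = asdict(cohort.config)
    cfg["region_length_range"] = list(cfg["region_length_range"])
    meta = {"config": cfg, "d1_mean": tr.d1_mean, "d1_sd": tr.d1_sd,
            "totals_by_type": [int(x) for x in cohort.totals_by_type]}
    (out / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
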