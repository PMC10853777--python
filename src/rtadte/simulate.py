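"""Count-level synthetic data with known assignment-ambiguity overdispersion.

The generator mimics what a lightweight quantifier emits, at desk scale:

* a transcriptome of genes with 1..K isoforms; each isoform routes a
  fraction ``ambiguity`` of its read mass into a class shared by all
  isoforms of its gene and the rest into a transcript-unique class;
* per-sample true expression drawn from a gamma distribution, so counts
  follow a (continuous) NB across replicates;
* class-level read counts drawn multinomially at the target library size,
  so column sums are conserved exactly;
* bootstrap resamples drawn multinomially over classes from the observed
  class frequencies, then re-assigned to member transcripts.

Re-assignment of a shared class is probabilistic and *correlated across
the reads of the class*: each realization re-draws the split proportions
from a Dirichlet centered on the abundance-proportional split (see
:func:`_assign_shared`), standing in for the per-bootstrap re-estimation
of assignment proportions that quantifiers perform. The concentration is
calibrated so that a class shared equally by K transcripts yields a
quasi-Poisson dispersion of K — one for unique classes, two when every
read is ambiguous between two transcripts, and monotone in the ambiguity
fraction. The same stochastic assignment is applied to the point-estimate
counts, which therefore come out fractional (as from a real quantifier)
and obey ``var(y) = sigma2 * mu + phi * mu^2``.

Ground truth ``sigma2`` is obtained by brute force (:func:`true_sigma2`),
never from the calibration argument, so estimator-recovery tests close the
loop independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .quant_io import QuantBundle

__all__ = [
    "SimTruth",
    "make_transcriptome",
    "draw_expression",
    "draw_counts_and_bootstraps",
    "true_sigma2",
    "build_scenario",
    "score_run",
]

DEFAULT_ISOFORM_DIST = {1: 0.35, 2: 0.25, 3: 0.20, 5: 0.10, 10: 0.10}
DEFAULT_LIB_SIZES = (250_000, 1_000_000)  # alternating over samples


@dataclass
class SimTruth:
    """Ground truth for a simulated experiment."""

    transcript_ids: list
    gene_ids: list                       # per transcript
    isoform_count: np.ndarray            # per transcript: isoforms of its gene
    unique_weight: np.ndarray            # per transcript, 1 - ambiguity share
    shared_groups: dict                  # K -> (G_K, K) member index array
    baseline_expression: np.ndarray      # pi_0, sums to 1
    bcv2: np.ndarray                     # generative NB dispersion phi_t
    de_labels: np.ndarray                # {-1, 0, +1}
    fold_change: np.ndarray              # group-2 multiplier, 1 where label 0
    group_labels: np.ndarray | None = None
    true_sigma2_: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    def class_weights_sum(self) -> np.ndarray:
        """Total class weight per transcript (unique + shared); must be 1."""
        w = self.unique_weight.copy()
        for members in self.shared_groups.values():
            w[members.ravel()] += 1.0 - self.unique_weight[members.ravel()]
        return w

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "transcript_id": self.transcript_ids,
            "gene_id": self.gene_ids,
            "isoform_count": self.isoform_count,
            "unique_weight": self.unique_weight,
            "baseline_expression": self.baseline_expression,
            "bcv2": self.bcv2,
            "de_label": self.de_labels,
            "fold_change": self.fold_change,
            "true_sigma2": (self.true_sigma2_ if self.true_sigma2_ is not None
                            else np.nan),
        })


def make_transcriptome(n_genes: int, isoforms_per_gene=None,
                       ambiguity: float = 0.5, seed: int = 0,
                       expression_sd: float = 1.2,
                       bcv2_base: float = 0.04,
                       bcv2_lowcount: float = 2.0,
                       ref_lib_size: float = 625_000.0) -> SimTruth:
    """Build a transcriptome skeleton with class structure and baselines.

    ``isoforms_per_gene`` may be an int (constant), a mapping value->prob,
    or an explicit array of per-gene isoform counts. With ``ambiguity = 0``
    every class is transcript-unique and downstream true overdispersion is
    1; single-isoform genes are always fully unique.
    """
    if not 0.0 <= ambiguity <= 1.0:
        raise DataError("ambiguity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if isoforms_per_gene is None:
        isoforms_per_gene = DEFAULT_ISOFORM_DIST
    if isinstance(isoforms_per_gene, dict):
        ks = np.array(sorted(isoforms_per_gene))
        ps = np.array([isoforms_per_gene[k] for k in ks], dtype=float)
        ps = ps / ps.sum()
        k_per_gene = rng.choice(ks, size=n_genes, p=ps)
    elif np.isscalar(isoforms_per_gene):
        k_per_gene = np.full(n_genes, int(isoforms_per_gene))
    else:
        k_per_gene = np.asarray(isoforms_per_gene, dtype=int)
        n_genes = len(k_per_gene)

    tids, gids, iso = [], [], []
    shared_groups: dict[int, list] = {}
    idx = 0
    for g, k in enumerate(k_per_gene):
        members = list(range(idx, idx + k))
        for t in members:
            tids.append(f"T{t:06d}")
            gids.append(f"G{g:05d}")
            iso.append(k)
        if k > 1 and ambiguity > 0:
            shared_groups.setdefault(int(k), []).append(members)
        idx += k
    T = idx
    iso = np.asarray(iso)
    unique_weight = np.where(iso > 1, 1.0 - ambiguity, 1.0)
    shared = {k: np.asarray(v, dtype=int) for k, v in shared_groups.items()}

    pi0 = np.exp(rng.normal(0.0, expression_sd, size=T))
    pi0 /= pi0.sum()
    mu0 = pi0 * ref_lib_size
    bcv2 = bcv2_base + bcv2_lowcount / np.maximum(mu0, 1.0)
    return SimTruth(
        transcript_ids=tids,
        gene_ids=gids,
        isoform_count=iso,
        unique_weight=unique_weight,
        shared_groups=shared,
        baseline_expression=pi0,
        bcv2=np.minimum(bcv2, 4.0),
        de_labels=np.zeros(T, dtype=int),
        fold_change=np.ones(T),
        provenance={"n_genes": int(n_genes), "ambiguity": float(ambiguity),
                    "seed": int(seed)},
    )


def set_differential_expression(truth: SimTruth, n_de: int, fc: float,
                                seed: int = 0) -> SimTruth:
    """Mark ``n_de`` random transcripts as DE at fold change ``fc``, split
    as evenly as possible between up and down."""
    rng = np.random.default_rng(seed)
    T = truth.n_transcripts
    if n_de > T:
        raise DataError(f"n_de={n_de} exceeds {T} transcripts")
    chosen = rng.choice(T, size=n_de, replace=False)
    n_up = n_de // 2 + (n_de % 2) * int(rng.integers(0, 2))
    labels = np.zeros(T, dtype=int)
    labels[chosen[:n_up]] = 1
    labels[chosen[n_up:]] = -1
    fold = np.ones(T)
    fold[labels == 1] = fc
    fold[labels == -1] = 1.0 / fc
    truth.de_labels = labels
    truth.fold_change = fold
    return truth


def draw_expression(truth: SimTruth, n_samples: int, group_labels=None,
                    seed: int = 0) -> np.ndarray:
    """Per-sample true expression proportions, gamma-distributed.

    Means are the baseline times the fold change for group-2 samples;
    the gamma shape is ``1 / bcv2`` so the coefficient of variation across
    replicates is ``sqrt(bcv2)``. Columns are renormalized to sum to 1.
    ``bcv2 = 0`` rows are held constant (the infinite-shape limit).
    """
    rng = np.random.default_rng(seed)
    if group_labels is None:
        group_labels = np.zeros(n_samples, dtype=int)
    group_labels = np.asarray(group_labels)
    if len(group_labels) != n_samples:
        raise DataError("group_labels length must equal n_samples")
    T = truth.n_transcripts
    pis = np.empty((T, n_samples))
    phi = truth.bcv2
    positive = phi > 0
    shape = np.where(positive, 1.0 / np.maximum(phi, 1e-12), 1.0)
    for i in range(n_samples):
        mean = truth.baseline_expression * np.where(group_labels[i] == 1,
                                                    truth.fold_change, 1.0)
        draw = np.where(
            positive,
            rng.gamma(shape, np.maximum(mean, 1e-300) / shape),
            mean,
        )
        pis[:, i] = draw / draw.sum()
    return pis


# ---------------------------------------------------------------------------
# class-level read generation
# ---------------------------------------------------------------------------

def _class_probs(truth: SimTruth, pi: np.ndarray):
    """Class probabilities for one sample: unique part then shared groups."""
    p_unique = pi * truth.unique_weight
    shared = []
    for k in sorted(truth.shared_groups):
        members = truth.shared_groups[k]
        amb = 1.0 - truth.unique_weight[members]  # ambiguity share per member
        shared.append((k, members, (pi[members] * amb).sum(axis=1)))
    return p_unique, shared


def _assign_shared(S: np.ndarray, member_pi: np.ndarray, k: int, rng) -> np.ndarray:
    """Correlated probabilistic assignment of shared-class reads.

    For each realization the split proportions of a class are re-drawn from
    a Dirichlet centered on the abundance-proportional split with
    concentration ``S / (k + 1)``, and the class count is divided
    fractionally according to the draw. The shared draw couples the reads
    of a class — the stand-in for per-bootstrap re-estimation of
    assignment proportions — and the concentration is calibrated so a
    class shared equally by K transcripts has var/mean = K (and a unique
    class stays Poisson). Counts are fractional, like quantifier output,
    and sum to the class count exactly.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = member_pi.sum(axis=1, keepdims=True)
        q = np.where(denom > 0, member_pi / np.maximum(denom, 1e-300), 1.0 / k)
    alpha = q * (S / (k + 1.0))[:, None]
    gam = rng.gamma(np.maximum(alpha, 0.0))
    tot = gam.sum(axis=1, keepdims=True)
    ok = tot[:, 0] > 0
    split = np.where(ok[:, None], gam / np.where(tot > 0, tot, 1.0), q)
    return split * S[:, None]


def _one_realization(truth: SimTruth, pi: np.ndarray, class_counts, shared_meta,
                     rng) -> np.ndarray:
    """Assign class-level counts to transcripts (one sample or bootstrap)."""
    T = truth.n_transcripts
    u = np.zeros(T)
    n_unique = T
    u += class_counts[:n_unique]
    offset = n_unique
    for k, members, _ in shared_meta:
        G = members.shape[0]
        S = class_counts[offset:offset + G]
        contrib = _assign_shared(S.astype(np.int64), pi[members], k, rng)
        u[members.ravel()] += contrib.ravel()
        offset += G
    return u


def draw_counts_and_bootstraps(truth: SimTruth, pis: np.ndarray,
                               lib_sizes, B: int, seed: int = 0) -> QuantBundle:
    """Simulate point-estimate counts and B bootstrap resamples per sample.

    Per sample, class counts are multinomial at the library size (columns
    conserve reads exactly); each bootstrap resamples the observed class
    frequencies multinomially at the same total before re-assignment.
    """
    rng = np.random.default_rng(seed)
    lib_sizes = np.asarray(lib_sizes, dtype=np.int64)
    T, n = pis.shape
    if len(lib_sizes) != n:
        raise DataError("lib_sizes length must equal the number of samples")
    counts = np.empty((T, n))
    boots = []
    for i in range(n):
        pi = pis[:, i]
        p_unique, shared_meta = _class_probs(truth, pi)
        p_all = np.concatenate([p_unique] + [s[2] for s in shared_meta]
                               ) if shared_meta else p_unique
        p_all = np.clip(p_all, 0.0, None)
        p_all = p_all / p_all.sum()
        S0 = rng.multinomial(lib_sizes[i], p_all)
        counts[:, i] = _one_realization(truth, pi, S0, shared_meta, rng)
        u = np.empty((T, B))
        if B > 0:
            p_boot = S0 / S0.sum()
            for b in range(B):
                Sb = rng.multinomial(lib_sizes[i], p_boot)
                u[:, b] = _one_realization(truth, pi, Sb, shared_meta, rng)
        boots.append(u)
    lengths = np.full(T, 1000)
    eff = np.full((T, n), 800.0)
    return QuantBundle(
        transcript_ids=list(truth.transcript_ids),
        lengths=lengths,
        effective_lengths=eff,
        counts=counts,
        bootstraps=boots,
        sample_ids=[f"sample{i + 1}" for i in range(n)],
        provenance={"format": "simulated", "seed": int(seed), "B": int(B)},
    )


def true_sigma2(truth: SimTruth, pis: np.ndarray, lib_sizes, n_mc: int = 200,
                seed: int = 12345) -> np.ndarray:
    """Brute-force ground-truth overdispersion: var/mean of fresh draws.

    For each sample, ``n_mc`` independent realizations are generated at the
    fixed true expression and the per-transcript variance/mean ratio is
    computed; ratios are averaged over samples (weighted by the transcript
    mean, so deeply sequenced samples dominate as they do in estimation).
    """
    rng = np.random.default_rng(seed)
    lib_sizes = np.asarray(lib_sizes, dtype=np.int64)
    T, n = pis.shape
    num = np.zeros(T)
    den = np.zeros(T)
    for i in range(n):
        pi = pis[:, i]
        p_unique, shared_meta = _class_probs(truth, pi)
        p_all = np.concatenate([p_unique] + [s[2] for s in shared_meta]
                               ) if shared_meta else p_unique
        p_all = np.clip(p_all, 0.0, None)
        p_all = p_all / p_all.sum()
        s = np.zeros(T)
        s2 = np.zeros(T)
        for _ in range(n_mc):
            Sb = rng.multinomial(lib_sizes[i], p_all)
            u = _one_realization(truth, pi, Sb, shared_meta, rng)
            s += u
            s2 += u * u
        mean = s / n_mc
        var = s2 / n_mc - mean ** 2
        var *= n_mc / (n_mc - 1)
        num += np.where(mean > 0, var, 0.0)
        den += mean
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return out


# ---------------------------------------------------------------------------
# scenario builders and scoring
# ---------------------------------------------------------------------------

def build_scenario(name: str, n_per_group: int = 5, n_transcripts: int = 5000,
                   n_de: int = 300, fc: float = 2.0, B: int = 100,
                   seed: int = 0, ambiguity: float = 0.5,
                   isoforms_per_gene=None, lib_sizes=None):
    """Build a two-group null or DE experiment; returns (bundle, truth).

    Library sizes default to an unbalanced alternating pattern. The number
    of genes is chosen so the expected transcript count matches
    ``n_transcripts``; the realized count varies slightly with the seed.
    """
    if name not in ("null", "de"):
        raise DataError(f"unknown scenario {name!r}; expected 'null' or 'de'")
    dist = isoforms_per_gene if isoforms_per_gene is not None else DEFAULT_ISOFORM_DIST
    if isinstance(dist, dict):
        mean_iso = sum(k * v for k, v in dist.items()) / sum(dist.values())
    elif np.isscalar(dist):
        mean_iso = float(dist)
    else:
        mean_iso = float(np.mean(dist))
    n_genes = max(1, int(round(n_transcripts / mean_iso)))
    truth = make_transcriptome(n_genes, dist, ambiguity, seed=seed)
    if name == "de":
        truth = set_differential_expression(truth, min(n_de, truth.n_transcripts),
                                            fc, seed=seed + 1)
    n = 2 * n_per_group
    groups = np.repeat([0, 1], n_per_group)
    if lib_sizes is None:
        lib_sizes = np.array([DEFAULT_LIB_SIZES[i % 2] for i in range(n)])
    pis = draw_expression(truth, n, group_labels=groups, seed=seed + 2)
    bundle = draw_counts_and_bootstraps(truth, pis, lib_sizes, B, seed=seed + 3)
    truth.group_labels = groups
    truth.provenance.update({"scenario": name, "lib_sizes": np.asarray(lib_sizes).tolist(),
                             "B": int(B), "n_per_group": int(n_per_group)})
    return bundle, truth


def score_run(results: pd.DataFrame, truth: SimTruth, alpha: float = 0.05) -> dict:
    """Power / observed FDR / type-I metrics of a DTE result against truth.

    ``power`` counts detections among true-DE transcripts that entered the
    test; ``observed_fdr`` uses the 0/0 := 0 convention; ``type1`` is the
    raw-p rate among null transcripts.
    """
    tmap = {t: i for i, t in enumerate(truth.transcript_ids)}
    ids = results["transcript_id"].tolist()
    missing = [t for t in ids if t not in tmap]
    if missing:
        raise DataError(f"result ids not present in truth (e.g. {missing[:3]})")
    idx = np.array([tmap[t] for t in ids])
    is_de = truth.de_labels[idx] != 0
    called = results["fdr"].to_numpy() <= alpha
    tp = int(np.sum(called & is_de))
    fp = int(np.sum(called & ~is_de))
    n_true = int(np.sum(is_de))
    n_null = int(np.sum(~is_de))
    p = results["p_value"].to_numpy()
    return {
        "power": tp / n_true if n_true else 0.0,
        "observed_fdr": fp / max(1, tp + fp),
        "type1": float(np.sum((p < alpha) & ~is_de)) / n_null if n_null else 0.0,
        "n_called": int(np.sum(called)),
        "n_tested": len(ids),
    }
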