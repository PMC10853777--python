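"""Expression filtering and composition normalization ahead of model fitting."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

__all__ = [
    "DTEDataset",
    "filter_by_expression",
    "tmm_norm_factors",
    "cpm",
    "ave_log_cpm",
]

_TOL = 1e-14


@dataclass
class DTEDataset:
    """Count matrix with library sizes, normalization factors and a design.

    ``counts`` may hold raw or uncertainty-scaled counts; both flow through
    the identical code path. ``norm_factors`` have geometric mean 1.
    """

    counts: np.ndarray
    transcript_ids: list
    sample_ids: list
    library_sizes: np.ndarray | None = None
    norm_factors: np.ndarray | None = None
    design: np.ndarray | None = None
    group_labels: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise DataError("counts must be finite and non-negative")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.norm_factors is None:
            self.norm_factors = np.ones(self.counts.shape[1])
        self.norm_factors = np.asarray(self.norm_factors, dtype=float)
        if np.any(self.norm_factors <= 0):
            raise DataError("norm_factors must be positive")
        if self.group_labels is not None:
            self.group_labels = np.asarray(self.group_labels)
        if self.design is not None:
            self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
            if np.linalg.matrix_rank(self.design) < self.design.shape[1]:
                raise DataError("design matrix is not of full column rank")

    @property
    def n_transcripts(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def effective_library_sizes(self) -> np.ndarray:
        return self.library_sizes * self.norm_factors

    def subset(self, keep: np.ndarray, note: str | None = None) -> "DTEDataset":
        prov = dict(self.provenance)
        if note:
            prov.setdefault("filters", []).append(note)
        return DTEDataset(
            counts=self.counts[keep],
            transcript_ids=[t for t, k in zip(self.transcript_ids, keep) if k],
            sample_ids=list(self.sample_ids),
            library_sizes=self.library_sizes,
            norm_factors=self.norm_factors,
            design=self.design,
            group_labels=self.group_labels,
            provenance=prov,
        )


def _min_group_size(ds: DTEDataset) -> int:
    if ds.group_labels is not None:
        _, counts = np.unique(ds.group_labels, return_counts=True)
        return int(counts.min())
    if ds.design is not None:
        # treat identical design rows as a group
        _, counts = np.unique(np.round(ds.design, 12), axis=0, return_counts=True)
        return int(counts.min())
    raise DataError("group labels or a design matrix are required for filtering")


def filter_by_expression(ds: DTEDataset, min_count: float = 10.0,
                         min_total: float = 15.0,
                         min_prop: float = 0.7) -> DTEDataset:
    """Keep transcripts with worthwhile expression for model fitting.

    A transcript is kept when its CPM is at least ``c`` in at least ``k``
    samples — ``c`` being ``min_count`` translated to the CPM scale of the
    median library size and ``k = min_prop * (smallest group size)`` — and
    its total count is at least ``min_total``. Comparisons carry a 1e-14
    tolerance so that integer products such as 0.7 * 10 = 7 behave exactly.
    """
    k = min_prop * _min_group_size(ds)
    med_lib = np.median(ds.library_sizes)
    if med_lib <= 0:
        raise DataError("median library size is zero")
    cpm_cutoff = min_count / med_lib * 1e6
    cpm_mat = ds.counts / ds.library_sizes[None, :] * 1e6
    n_pass = (cpm_mat >= cpm_cutoff).sum(axis=1)
    keep = (n_pass >= k - _TOL) & (ds.counts.sum(axis=1) >= min_total - _TOL)
    if not np.any(keep):
        raise DataError(
            f"filtering removed all {ds.n_transcripts} transcripts "
            f"(cpm cutoff {cpm_cutoff:.3g} in >= {k:.3g} samples)"
        )
    return ds.subset(keep, note=f"filter_by_expression kept {int(keep.sum())}/{len(keep)}")


def tmm_norm_factors(ds: DTEDataset, trim_logratio: float = 0.3,
                     trim_abs: float = 0.05) -> DTEDataset:
    """Trimmed-mean-of-M-values composition normalization factors.

    The reference sample is the one whose upper quartile of count
    proportions is closest to the mean upper quartile. Log ratios (M) are
    doubly trimmed, by M and by average abundance (A), and combined with
    inverse-variance weights; factors are rescaled to geometric mean 1.
    """
    if ds.n_samples < 2:
        raise DataError("TMM needs at least two samples")
    lib = ds.library_sizes
    if np.any(lib <= 0):
        raise DataError("sample with zero library size")
    props = ds.counts / lib[None, :]
    uq = np.quantile(props, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(ds.n_samples)
    for j in range(ds.n_samples):
        factors[j] = _tmm_pair(ds.counts[:, j], ds.counts[:, ref], lib[j], lib[ref],
                               trim_logratio, trim_abs)
    factors = factors / np.exp(np.mean(np.log(factors)))
    out = DTEDataset(
        counts=ds.counts,
        transcript_ids=list(ds.transcript_ids),
        sample_ids=list(ds.sample_ids),
        library_sizes=ds.library_sizes,
        norm_factors=factors,
        design=ds.design,
        group_labels=ds.group_labels,
        provenance=dict(ds.provenance),
    )
    out.provenance["tmm"] = {"ref_sample": ds.sample_ids[ref],
                             "trim_logratio": trim_logratio, "trim_abs": trim_abs}
    return out


def _tmm_pair(obs, ref, lib_obs, lib_ref, trim_logratio, trim_abs) -> float:
    ok = (obs > 0) & (ref > 0)
    if not np.any(ok):
        return 1.0
    po, pr = obs[ok] / lib_obs, ref[ok] / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # delta-method precision weights on the proportion scale; exactly
    # invariant to rescaling either column (depth goes into the library size)
    w = (1.0 - po) / po + (1.0 - pr) / pr
    if np.max(np.abs(m)) < 1e-6:  # identical proportions up to depth
        return 1.0
    n = m.size
    lo_m = int(np.floor(n * trim_logratio)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_abs)) + 1
    hi_a = n + 1 - lo_a
    rank_m = np.argsort(np.argsort(m, kind="stable"), kind="stable") + 1
    rank_a = np.argsort(np.argsort(a, kind="stable"), kind="stable") + 1
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep) or np.sum(1.0 / w[keep]) == 0:
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def cpm(ds: DTEDataset, log: bool = False, prior_count: float = 2.0) -> np.ndarray:
    """Counts per million on effective library sizes.

    The log version damps low counts with a library-size-proportional prior
    count so zero counts map to a finite value.
    """
    eff = ds.effective_library_sizes
    if not log:
        return ds.counts / eff[None, :] * 1e6
    pc = prior_count * eff / eff.mean()
    return np.log2((ds.counts + pc[None, :]) / (eff + 2 * pc)[None, :] * 1e6)


def ave_log_cpm(ds: DTEDataset, prior_count: float = 2.0) -> np.ndarray:
    """Average abundance per transcript, in log2 CPM with prior-count damping."""
    eff = ds.effective_library_sizes
    pc = prior_count * eff / eff.mean()
    dampened = (ds.counts + pc[None, :]) / (eff + 2 * pc)[None, :]
    return np.log2(dampened.mean(axis=1) * 1e6)
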