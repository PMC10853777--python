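"""Readers and writers for transcript quantifications with bootstrap resamples.

Three dialects are supported:

* Salmon output directories (``quant.sf`` + ``aux_info/``),
* kallisto output directories (``abundance.h5``),
* a plain tab-delimited fallback (counts table + per-sample bootstrap tables).

All counts are kept as continuous reals end-to-end; nothing is rounded.
The writers emit exactly the dialect their reader consumes, so fixture
directories for tests can be generated on the fly.
"""

from __future__ import annotations

import gzip
import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "QuantBundle",
    "read_salmon",
    "read_kallisto",
    "read_plain",
    "write_salmon_fixture",
    "write_kallisto_fixture",
]

_LIBSIZE_RTOL = 1e-8


@dataclass
class QuantBundle:
    """Per-sample transcript quantifications with bootstrap resamples.

    Attributes
    ----------
    transcript_ids : list of str
        Shared transcript identifiers; every sample is aligned to this order.
    lengths : ndarray, shape (T,)
        Annotated transcript length in bp.
    effective_lengths : ndarray, shape (T, n)
        Per-sample effective lengths. Carried through for export; the core
        method operates on counts only.
    counts : ndarray, shape (T, n)
        Point-estimate transcript counts; fractional values allowed.
    bootstraps : list of ndarray
        One ``(T, B_i)`` matrix per sample; ``B_i`` may be 0.
    sample_ids : list of str
    provenance : dict
        Free-form record of where the data came from and how it was decoded.
    """

    transcript_ids: list
    lengths: np.ndarray
    effective_lengths: np.ndarray
    counts: np.ndarray
    bootstraps: list
    sample_ids: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths)
        self.effective_lengths = np.atleast_2d(np.asarray(self.effective_lengths, dtype=float))
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        self.bootstraps = [np.asarray(b, dtype=float).reshape(self.n_transcripts, -1)
                           for b in self.bootstraps]
        self.validate()

    # -- basic shape accessors -------------------------------------------------
    @property
    def n_transcripts(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bootstraps(self) -> np.ndarray:
        """B_i per sample."""
        return np.array([b.shape[1] for b in self.bootstraps], dtype=int)

    @property
    def library_sizes(self) -> np.ndarray:
        """N_i, defined as the column sums of the count matrix."""
        return self.counts.sum(axis=0)

    def validate(self):
        T, n = self.counts.shape
        if len(self.transcript_ids) != T:
            raise DataError(f"{len(self.transcript_ids)} transcript ids for {T} count rows")
        if len(self.sample_ids) != n:
            raise DataError(f"{len(self.sample_ids)} sample ids for {n} count columns")
        if len(self.bootstraps) != n:
            raise DataError(f"{len(self.bootstraps)} bootstrap matrices for {n} samples")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise DataError("counts must be finite and non-negative")
        for sid, b in zip(self.sample_ids, self.bootstraps):
            if b.shape[0] != T:
                raise DataError(f"bootstrap matrix for sample {sid!r} has {b.shape[0]} rows, expected {T}")
            if not np.all(np.isfinite(b)) or np.any(b < 0):
                raise DataError(f"bootstraps for sample {sid!r} must be finite and non-negative")
        if self.effective_lengths.shape != (T, n):
            raise DataError("effective_lengths must be transcripts x samples")

    def reorder(self, new_ids) -> "QuantBundle":
        """Return a bundle with rows permuted to match ``new_ids``."""
        idx = {t: i for i, t in enumerate(self.transcript_ids)}
        if set(new_ids) != set(idx):
            raise DataError("transcript id sets differ; cannot reorder")
        perm = np.array([idx[t] for t in new_ids])
        return QuantBundle(
            transcript_ids=list(new_ids),
            lengths=self.lengths[perm],
            effective_lengths=self.effective_lengths[perm],
            counts=self.counts[perm],
            bootstraps=[b[perm] for b in self.bootstraps],
            sample_ids=list(self.sample_ids),
            provenance=dict(self.provenance),
        )


# ---------------------------------------------------------------------------
# Salmon dialect
# ---------------------------------------------------------------------------

def _read_one_salmon(d: str):
    quant = os.path.join(d, "quant.sf")
    if not os.path.exists(quant):
        raise DataError(f"missing quant.sf in {d}")
    tab = pd.read_csv(quant, sep="\t")
    for col in ("Name", "Length", "EffectiveLength", "NumReads"):
        if col not in tab.columns:
            raise DataError(f"{quant}: missing column {col!r}")
    meta_path = os.path.join(d, "aux_info", "meta_info.json")
    num_boot = 0
    samp_type = None
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            meta = json.load(fh)
        num_boot = int(meta.get("num_bootstraps", 0))
        samp_type = meta.get("samp_type")
    if samp_type == "gibbs" and num_boot > 0:
        warnings.warn(
            f"{d}: inferential replicates are Gibbs posterior samples, not "
            "bootstraps; treating them as bootstraps",
            stacklevel=3,
        )
    ids = tab["Name"].astype(str).tolist()
    boots = np.empty((len(ids), 0))
    dtype_used = None
    if num_boot > 0:
        bpath = os.path.join(d, "aux_info", "bootstrap", "bootstraps.gz")
        npath = os.path.join(d, "aux_info", "bootstrap", "names.tsv.gz")
        if not os.path.exists(bpath):
            raise DataError(f"{d}: meta_info.json declares {num_boot} bootstraps but {bpath} is missing")
        with gzip.open(npath, "rt") as fh:
            bnames = fh.read().rstrip("\n").split("\t")
        with gzip.open(bpath, "rb") as fh:
            raw = fh.read()
        T = len(bnames)
        # Salmon has emitted both double and int streams across versions:
        # auto-detect by byte length, preferring double on ambiguity.
        if len(raw) == num_boot * T * 8:
            vals = np.frombuffer(raw, dtype="<f8")
            dtype_used = "float64"
        elif len(raw) == num_boot * T * 4:
            vals = np.frombuffer(raw, dtype="<i4").astype(float)
            dtype_used = "int32"
        else:
            raise DataError(
                f"{bpath}: stream of {len(raw)} bytes matches neither "
                f"{num_boot}x{T} doubles nor 4-byte integers"
            )
        boots = vals.reshape(num_boot, T).T
        if bnames != ids:
            if set(bnames) != set(ids):
                raise DataError(f"{d}: bootstrap transcript ids differ from quant.sf ids")
            order = {t: i for i, t in enumerate(bnames)}
            boots = boots[np.array([order[t] for t in ids])]
    return ids, tab, boots, dtype_used, samp_type


def read_salmon(dirs) -> QuantBundle:
    """Read one or more Salmon quantification directories into a bundle.

    Counts come from the ``NumReads`` column of ``quant.sf``; bootstraps are
    decoded from ``aux_info/bootstrap/bootstraps.gz``. Transcript order is
    reconciled across samples by identifier; differing id *sets* are fatal.
    """
    dirs = [str(d) for d in dirs]
    if not dirs:
        raise DataError("no Salmon directories given")
    ref_ids = None
    counts, efflens, boots, sids = [], [], [], []
    lengths = None
    prov = {"format": "salmon", "dirs": dirs, "bootstrap_dtype": [], "samp_type": []}
    for d in dirs:
        ids, tab, b, dtype_used, samp_type = _read_one_salmon(d)
        prov["bootstrap_dtype"].append(dtype_used)
        prov["samp_type"].append(samp_type)
        if ref_ids is None:
            ref_ids = ids
            lengths = tab["Length"].to_numpy()
            order = np.arange(len(ids))
        else:
            if set(ids) != set(ref_ids):
                raise DataError(f"{d}: transcript id set differs from {dirs[0]}")
            pos = {t: i for i, t in enumerate(ids)}
            order = np.array([pos[t] for t in ref_ids])
        counts.append(tab["NumReads"].to_numpy(dtype=float)[order])
        efflens.append(tab["EffectiveLength"].to_numpy(dtype=float)[order])
        boots.append(b[order] if b.size else np.empty((len(ref_ids), 0)))
        sids.append(os.path.basename(os.path.normpath(d)))
    return QuantBundle(
        transcript_ids=list(ref_ids),
        lengths=lengths,
        effective_lengths=np.column_stack(efflens),
        counts=np.column_stack(counts),
        bootstraps=boots,
        sample_ids=sids,
        provenance=prov,
    )


def write_salmon_fixture(bundle: QuantBundle, out_dir) -> str:
    """Write ``bundle`` as Salmon-dialect directories (one per sample).

    Returns the root directory; sample directories are named after
    ``bundle.sample_ids``. ``read_salmon`` on those directories reproduces
    the bundle to full float precision.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    T = bundle.n_transcripts
    for j, sid in enumerate(bundle.sample_ids):
        d = os.path.join(out_dir, sid)
        os.makedirs(os.path.join(d, "aux_info", "bootstrap"), exist_ok=True)
        el = bundle.effective_lengths[:, j]
        y = bundle.counts[:, j]
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(el > 0, y / np.maximum(el, 1e-12), 0.0)
        tpm = rate / rate.sum() * 1e6 if rate.sum() > 0 else np.zeros(T)
        tab = pd.DataFrame({
            "Name": bundle.transcript_ids,
            "Length": bundle.lengths.astype(int),
            "EffectiveLength": el,
            "TPM": tpm,
            "NumReads": y,
        })
        tab.to_csv(os.path.join(d, "quant.sf"), sep="\t", index=False, float_format="%.17g")
        B = bundle.bootstraps[j].shape[1]
        meta = {"num_bootstraps": B, "samp_type": "bootstrap", "num_valid_targets": T}
        with open(os.path.join(d, "aux_info", "meta_info.json"), "w") as fh:
            json.dump(meta, fh)
        if B > 0:
            with gzip.open(os.path.join(d, "aux_info", "bootstrap", "names.tsv.gz"), "wt") as fh:
                fh.write("\t".join(bundle.transcript_ids) + "\n")
            stream = np.ascontiguousarray(bundle.bootstraps[j].T, dtype="<f8")
            with gzip.open(os.path.join(d, "aux_info", "bootstrap", "bootstraps.gz"), "wb") as fh:
                fh.write(stream.tobytes())
    return out_dir


# ---------------------------------------------------------------------------
# kallisto dialect
# ---------------------------------------------------------------------------

def read_kallisto(dirs) -> QuantBundle:
    """Read kallisto ``abundance.h5`` directories into a bundle."""
    import h5py

    dirs = [str(d) for d in dirs]
    if not dirs:
        raise DataError("no kallisto directories given")
    ref_ids = None
    counts, efflens, boots, sids = [], [], [], []
    lengths = None
    for d in dirs:
        path = os.path.join(d, "abundance.h5")
        if not os.path.exists(path):
            raise DataError(f"missing abundance.h5 in {d}")
        with h5py.File(path, "r") as h5:
            for ds in ("est_counts", "aux/ids", "aux/eff_lengths", "aux/lengths", "aux/num_bootstrap"):
                if ds not in h5:
                    raise DataError(f"{path}: missing dataset /{ds}")
            ids = [t.decode() if isinstance(t, bytes) else str(t) for t in h5["aux/ids"][:]]
            y = h5["est_counts"][:].astype(float)
            el = h5["aux/eff_lengths"][:].astype(float)
            ln = h5["aux/lengths"][:]
            B = int(np.asarray(h5["aux/num_bootstrap"][:]).ravel()[0])
            bs_keys = sorted(
                (k for k in h5.get("bootstrap", {})),
                key=lambda k: int(k[2:]),
            ) if "bootstrap" in h5 else []
            if B != len(bs_keys):
                raise DataError(
                    f"{path}: num_bootstrap={B} but {len(bs_keys)} bs* datasets present"
                )
            b = (np.column_stack([h5[f"bootstrap/{k}"][:] for k in bs_keys]).astype(float)
                 if B > 0 else np.empty((len(ids), 0)))
        if ref_ids is None:
            ref_ids, lengths = ids, np.asarray(ln)
            order = np.arange(len(ids))
        else:
            if set(ids) != set(ref_ids):
                raise DataError(f"{d}: transcript id set differs from {dirs[0]}")
            pos = {t: i for i, t in enumerate(ids)}
            order = np.array([pos[t] for t in ref_ids])
        counts.append(y[order])
        efflens.append(el[order])
        boots.append(b[order] if b.size else b)
        sids.append(os.path.basename(os.path.normpath(d)))
    return QuantBundle(
        transcript_ids=list(ref_ids),
        lengths=lengths,
        effective_lengths=np.column_stack(efflens),
        counts=np.column_stack(counts),
        bootstraps=boots,
        sample_ids=sids,
        provenance={"format": "kallisto", "dirs": dirs},
    )


def write_kallisto_fixture(bundle: QuantBundle, out_dir) -> str:
    """Write ``bundle`` as kallisto-dialect directories (one per sample)."""
    import h5py

    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    for j, sid in enumerate(bundle.sample_ids):
        d = os.path.join(out_dir, sid)
        os.makedirs(d, exist_ok=True)
        B = bundle.bootstraps[j].shape[1]
        with h5py.File(os.path.join(d, "abundance.h5"), "w") as h5:
            h5.create_dataset("est_counts", data=bundle.counts[:, j])
            aux = h5.create_group("aux")
            aux.create_dataset("ids", data=np.array([t.encode() for t in bundle.transcript_ids]))
            aux.create_dataset("eff_lengths", data=bundle.effective_lengths[:, j])
            aux.create_dataset("lengths", data=bundle.lengths.astype(np.int32))
            aux.create_dataset("num_bootstrap", data=np.array([B], dtype=np.int32))
            grp = h5.create_group("bootstrap")
            for b in range(B):
                grp.create_dataset(f"bs{b}", data=bundle.bootstraps[j][:, b])
    return out_dir


# ---------------------------------------------------------------------------
# plain tab-delimited dialect
# ---------------------------------------------------------------------------

def _read_table(path):
    try:
        tab = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"{path}: {exc}") from exc
    bad = tab.apply(lambda col: pd.to_numeric(col, errors="coerce")).isna() & tab.notna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0][0]) + 2  # +header +1-based
        raise DataError(f"{path}: non-numeric cell at line {row}")
    return tab.astype(float)


def read_plain(counts_path, bootstrap_paths=None) -> QuantBundle:
    """Read the plain dialect: a counts TSV plus optional per-sample bootstrap TSVs.

    ``bootstrap_paths`` is a sequence aligned with the count columns; when
    omitted the bundle has ``B_i = 0`` and is only usable for the raw-count
    pipeline.
    """
    tab = _read_table(counts_path)
    ids = [str(t) for t in tab.index]
    sids = [str(s) for s in tab.columns]
    counts = tab.to_numpy()
    boots = []
    if bootstrap_paths:
        if len(bootstrap_paths) != len(sids):
            raise DataError(
                f"{len(bootstrap_paths)} bootstrap files for {len(sids)} samples"
            )
        for path in bootstrap_paths:
            b = _read_table(path)
            bids = [str(t) for t in b.index]
            if set(bids) != set(ids):
                missing = sorted(set(ids) - set(bids))[:3]
                raise DataError(f"{path}: transcript ids do not match counts table "
                                f"(e.g. missing {missing})")
            boots.append(b.loc[ids].to_numpy())
    else:
        boots = [np.empty((len(ids), 0)) for _ in sids]
    T = len(ids)
    return QuantBundle(
        transcript_ids=ids,
        lengths=np.full(T, -1),
        effective_lengths=np.full((T, len(sids)), np.nan),
        counts=counts,
        bootstraps=boots,
        sample_ids=sids,
        provenance={"format": "plain", "counts_path": str(counts_path)},
    )
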