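import gzip
import json
import os
import shutil

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtadte import (
    DataError,
    QuantBundle,
    read_kallisto,
    read_plain,
    read_salmon,
    write_kallisto_fixture,
    write_salmon_fixture,
)

from conftest import random_bundle


def assert_bundles_equal(a, b, tol=1e-9):
    assert a.transcript_ids == b.transcript_ids
    assert a.sample_ids == b.sample_ids
    np.testing.assert_allclose(a.counts, b.counts, atol=tol, rtol=0)
    np.testing.assert_array_equal(a.lengths, b.lengths)
    np.testing.assert_allclose(a.effective_lengths, b.effective_lengths, atol=tol, rtol=0)
    for x, y in zip(a.bootstraps, b.bootstraps):
        np.testing.assert_allclose(x, y, atol=tol, rtol=0)


def sample_dirs(root, bundle):
    return [os.path.join(root, s) for s in bundle.sample_ids]


class TestSalmon:
    def test_round_trip(self, rng, tmp_path):
        bundle = random_bundle(rng, T=5, n=2, B=3)
        root = write_salmon_fixture(bundle, tmp_path / "salmon")
        got = read_salmon(sample_dirs(root, bundle))
        assert got.bootstraps[0].shape == (5, 3)
        assert_bundles_equal(bundle, got)

    def test_round_trip_fractional_counts(self, rng, tmp_path):
        bundle = random_bundle(rng, T=10, n=2, B=5)
        bundle.counts[0, 0] = 2.5
        root = write_salmon_fixture(bundle, tmp_path / "salmon")
        got = read_salmon(sample_dirs(root, bundle))
        assert got.counts[0, 0] == pytest.approx(2.5, abs=1e-9)

    def test_zero_bootstraps(self, rng, tmp_path):
        bundle = random_bundle(rng, T=4, n=2, B=0)
        root = write_salmon_fixture(bundle, tmp_path / "salmon")
        got = read_salmon(sample_dirs(root, bundle))
        assert list(got.n_bootstraps) == [0, 0]

    def test_missing_quant_sf_fatal(self, tmp_path):
        os.makedirs(tmp_path / "empty")
        with pytest.raises(DataError, match="quant.sf"):
            read_salmon([tmp_path / "empty"])

    def test_permuted_sample_dir_aligned(self, rng, tmp_path):
        """A sample directory with permuted transcript order reads identically."""
        bundle = random_bundle(rng, T=8, n=2, B=4)
        root = write_salmon_fixture(bundle, tmp_path / "salmon")
        perm = rng.permutation(8)
        permuted = bundle.reorder([bundle.transcript_ids[i] for i in perm])
        # rewrite only the second sample dir in permuted order
        single = QuantBundle(
            transcript_ids=permuted.transcript_ids,
            lengths=permuted.lengths,
            effective_lengths=permuted.effective_lengths[:, [1]],
            counts=permuted.counts[:, [1]],
            bootstraps=[permuted.bootstraps[1]],
            sample_ids=[bundle.sample_ids[1]],
        )
        shutil.rmtree(os.path.join(root, bundle.sample_ids[1]))
        write_salmon_fixture(single, root)
        got = read_salmon(sample_dirs(root, bundle))
        assert_bundles_equal(bundle, got)

    def test_id_set_mismatch_fatal(self, rng, tmp_path):
        bundle = random_bundle(rng, T=5, n=1, B=2)
        other = random_bundle(rng, T=5, n=1, B=2)
        other.transcript_ids[0] = "DIFFERENT"
        other.sample_ids[0] = "s1"
        write_salmon_fixture(bundle, tmp_path / "salmon")
        write_salmon_fixture(other, tmp_path / "salmon")
        with pytest.raises(DataError, match="id set differs"):
            read_salmon([tmp_path / "salmon" / "s0", tmp_path / "salmon" / "s1"])

    def test_int32_stream_decoded(self, rng, tmp_path):
        bundle = random_bundle(rng, T=6, n=1, B=3)
        bundle.bootstraps[0] = np.round(bundle.bootstraps[0])
        root = write_salmon_fixture(bundle, tmp_path / "salmon")
        bpath = os.path.join(root, "s0", "aux_info", "bootstrap", "bootstraps.gz")
        stream = np.ascontiguousarray(bundle.bootstraps[0].T, dtype="<i4")
        with gzip.open(bpath, "wb") as fh:
            fh.write(stream.tobytes())
        got = read_salmon([os.path.join(root, "s0")])
        np.testing.assert_allclose(got.bootstraps[0], bundle.bootstraps[0])
        assert got.provenance["bootstrap_dtype"] == ["int32"]

    def test_bad_stream_length_fatal(self, rng, tmp_path):
        bundle = random_bundle(rng, T=6, n=1, B=3)
        root = write_salmon_fixture(bundle, tmp_path / "salmon")
        bpath = os.path.join(root, "s0", "aux_info", "bootstrap", "bootstraps.gz")
        with gzip.open(bpath, "rb") as fh:
            raw = fh.read()
        with gzip.open(bpath, "wb") as fh:
            fh.write(raw[:-5])
        with pytest.raises(DataError, match="stream"):
            read_salmon([os.path.join(root, "s0")])

    def test_gibbs_samples_warn(self, rng, tmp_path):
        bundle = random_bundle(rng, T=4, n=1, B=3)
        root = write_salmon_fixture(bundle, tmp_path / "salmon")
        meta_path = os.path.join(root, "s0", "aux_info", "meta_info.json")
        with open(meta_path) as fh:
            meta = json.load(fh)
        meta["samp_type"] = "gibbs"
        with open(meta_path, "w") as fh:
            json.dump(meta, fh)
        with pytest.warns(UserWarning, match="Gibbs"):
            got = read_salmon([os.path.join(root, "s0")])
        np.testing.assert_allclose(got.bootstraps[0], bundle.bootstraps[0])

    def test_library_sizes_are_column_sums(self, rng, tmp_path):
        bundle = random_bundle(rng, T=7, n=3, B=2)
        root = write_salmon_fixture(bundle, tmp_path / "salmon")
        got = read_salmon(sample_dirs(root, bundle))
        np.testing.assert_allclose(got.library_sizes, got.counts.sum(axis=0), rtol=1e-8)


class TestKallisto:
    def test_round_trip(self, rng, tmp_path):
        bundle = random_bundle(rng, T=4, n=2, B=2)
        root = write_kallisto_fixture(bundle, tmp_path / "kal")
        got = read_kallisto(sample_dirs(root, bundle))
        assert_bundles_equal(bundle, got)

    def test_zero_bootstraps(self, rng, tmp_path):
        bundle = random_bundle(rng, T=4, n=1, B=0)
        root = write_kallisto_fixture(bundle, tmp_path / "kal")
        got = read_kallisto(sample_dirs(root, bundle))
        assert got.bootstraps[0].shape == (4, 0)

    def test_fractional_counts_not_rounded(self, rng, tmp_path):
        bundle = random_bundle(rng, T=4, n=1, B=1)
        bundle.counts[2, 0] = 2.5
        root = write_kallisto_fixture(bundle, tmp_path / "kal")
        got = read_kallisto(sample_dirs(root, bundle))
        assert got.counts[2, 0] == 2.5

    def test_num_bootstrap_mismatch_fatal(self, rng, tmp_path):
        import h5py

        bundle = random_bundle(rng, T=4, n=1, B=3)
        root = write_kallisto_fixture(bundle, tmp_path / "kal")
        path = os.path.join(root, "s0", "abundance.h5")
        with h5py.File(path, "a") as h5:
            del h5["bootstrap/bs2"]
        with pytest.raises(DataError, match="bs"):
            read_kallisto([os.path.join(root, "s0")])

    def test_missing_dataset_fatal(self, rng, tmp_path):
        import h5py

        bundle = random_bundle(rng, T=4, n=1, B=1)
        root = write_kallisto_fixture(bundle, tmp_path / "kal")
        path = os.path.join(root, "s0", "abundance.h5")
        with h5py.File(path, "a") as h5:
            del h5["aux/eff_lengths"]
        with pytest.raises(DataError, match="eff_lengths"):
            read_kallisto([os.path.join(root, "s0")])


class TestPlain:
    def _write(self, tmp_path, rng, T=3, n=2, B=4):
        ids = [f"TX{i}" for i in range(T)]
        counts = rng.uniform(0, 50, (T, n))
        cpath = tmp_path / "counts.tsv"
        with open(cpath, "w") as fh:
            fh.write("id\t" + "\t".join(f"s{j}" for j in range(n)) + "\n")
            for i, t in enumerate(ids):
                fh.write(t + "\t" + "\t".join(f"{v:.10g}" for v in counts[i]) + "\n")
        bpaths = []
        boots = []
        for j in range(n):
            b = rng.uniform(0, 50, (T, B))
            boots.append(b)
            bp = tmp_path / f"boot{j}.tsv"
            with open(bp, "w") as fh:
                fh.write("id\t" + "\t".join(f"b{k}" for k in range(B)) + "\n")
                for i, t in enumerate(ids):
                    fh.write(t + "\t" + "\t".join(f"{v:.10g}" for v in b[i]) + "\n")
            bpaths.append(bp)
        return cpath, bpaths, counts, boots

    def test_round_trip(self, tmp_path, rng):
        cpath, bpaths, counts, boots = self._write(tmp_path, rng)
        got = read_plain(cpath, bpaths)
        assert got.n_bootstraps.tolist() == [4, 4]
        np.testing.assert_allclose(got.counts, counts, rtol=1e-9)
        np.testing.assert_allclose(got.bootstraps[1], boots[1], rtol=1e-9)

    def test_counts_only(self, tmp_path, rng):
        cpath, _, counts, _ = self._write(tmp_path, rng)
        got = read_plain(cpath)
        assert got.n_bootstraps.tolist() == [0, 0]

    def test_missing_transcript_fatal(self, tmp_path, rng):
        cpath, bpaths, _, _ = self._write(tmp_path, rng)
        lines = open(bpaths[0]).readlines()
        with open(bpaths[0], "w") as fh:
            fh.writelines(lines[:-1])
        with pytest.raises(DataError, match="ids do not match"):
            read_plain(cpath, bpaths)

    def test_non_numeric_cell_fatal(self, tmp_path, rng):
        cpath, _, _, _ = self._write(tmp_path, rng)
        with open(cpath, "a") as fh:
            fh.write("TXbad\tfoo\t1.0\n")
        with pytest.raises(DataError, match="line"):
            read_plain(cpath)


class TestBundleInvariants:
    def test_negative_counts_rejected(self, rng):
        with pytest.raises(DataError):
            QuantBundle(["a"], [100], [[100.0]], [[-1.0]], [np.empty((1, 0))], ["s"])

    def test_reorder_identity(self, small_bundle, rng):
        perm = rng.permutation(small_bundle.n_transcripts)
        ids = [small_bundle.transcript_ids[i] for i in perm]
        back = small_bundle.reorder(ids).reorder(small_bundle.transcript_ids)
        np.testing.assert_array_equal(back.counts, small_bundle.counts)

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10_000), T=st.integers(1, 12),
           n=st.integers(1, 3), B=st.integers(0, 6))
    def test_salmon_round_trip_property(self, tmp_path_factory, seed, T, n, B):
        rng = np.random.default_rng(seed)
        bundle = random_bundle(rng, T=T, n=n, B=B)
        root = write_salmon_fixture(bundle, tmp_path_factory.mktemp("rt"))
        got = read_salmon(sample_dirs(root, bundle))
        assert_bundles_equal(bundle, got)
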