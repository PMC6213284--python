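import numpy as np
import pytest
from hypothesis import settings

from occudyn.formats_io import GenomicRegion, SignalTrack
from occudyn.synthetic import SyntheticConfig, generate_dataset

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def make_track(triples, library_size=1e6, chrom="chr1", label=""):
    """Build a one-chromosome SignalTrack from (start, end, value) triples."""
    arr = np.array(triples, dtype=float).reshape(-1, 3)
    return SignalTrack(
        {chrom: (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])},
        library_size=library_size,
        label=label,
    )


def region(chrom, start, end, name=None):
    return GenomicRegion(chrom, start, end, name)


@pytest.fixture(scope="session")
def small_dataset():
    """A small zero-noise bundle: every call must recover planted truth exactly."""
    cfg = SyntheticConfig(
        n_class_i=20,
        n_class_ii=15,
        n_kept_nanog_only=2,
        n_kept_both=3,
        n_oct4_only=8,
        n_nanog_only=5,
        n_gained_oct4=5,
        n_gained_nanog=2,
        n_both_pairs=3,
        n_null_genes=100,
        genome_length=1_500_000,
        noise_sigma=0.0,
    )
    return generate_dataset(cfg, seed=11)


@pytest.fixture(scope="session")
def small_bundle_dir(small_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    small_dataset.write(outdir)
    return outdir
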