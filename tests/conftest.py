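import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from chipsim import fixtures as fx
from chipsim.model_params import ChipModel


@pytest.fixture(scope="session")
def toy_ref():
    """50 kb single-chromosome reference, deterministic."""
    spec = fx.ToySpec(chrom_length=50_000, seed=11)
    return fx.make_reference(spec)


@pytest.fixture(scope="session")
def toy_ref_lengths(toy_ref):
    return {c: len(s) for c, s in toy_ref.items()}


@pytest.fixture(scope="session")
def toy_peaks(toy_ref_lengths):
    spec = fx.ToySpec(chrom_length=50_000, n_peaks=5, peak_length=(800, 1200), seed=11)
    return fx.make_peaks(spec, toy_ref_lengths)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def write_sam(placements, ref_lengths, readlen, path):
    """Idealized paired-end SAM: one leftmost-mate record per pair."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, L in ref_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{L}\n")
        order = np.lexsort((placements.starts, placements.chrom_ids))
        for i in order:
            chrom = placements.chroms[placements.chrom_ids[i]]
            start = int(placements.starts[i])
            end = int(placements.ends[i])
            fh.write(
                f"r{i}\t67\t{chrom}\t{start + 1}\t60\t{readlen}M\t=\t"
                f"{end - readlen + 1}\t{end - start}\t*\t*\n"
            )


@pytest.fixture(scope="session")
def clean_model():
    return ChipModel(frag_shape=4.0, frag_scale=50.0, f=0.05, s=0.5, pcr_p=0.9)
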