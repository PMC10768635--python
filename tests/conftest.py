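import numpy as np
import pytest

from tigers.completion import CPFactors, TTCores, cp_reconstruct, tt_reconstruct


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def planted_cp():
    """Noise-free rank-2 CP tensor of shape 4 x 20 x 25 with its factors."""
    rng = np.random.default_rng(7)
    factors = CPFactors([rng.normal(size=(i, 2)) for i in (4, 20, 25)])
    return factors, cp_reconstruct(factors)


@pytest.fixture
def planted_tt():
    """Noise-free TT tensor of shape 4 x 20 x 25 with ranks {1,2,2,1}."""
    rng = np.random.default_rng(8)
    cores = TTCores(
        [rng.normal(size=(1, 4, 2)), rng.normal(size=(2, 20, 2)), rng.normal(size=(2, 25, 1))]
    )
    return cores, tt_reconstruct(cores)


def write_10x_dir(path, header, entries, genes, barcodes):
    """Write a minimal 10x-style directory from explicit MTX lines."""
    lines = ["%%MatrixMarket matrix coordinate integer general", header]
    lines += entries
    (path / "matrix.mtx").write_text("\n".join(lines) + "\n")
    (path / "features.tsv").write_text("".join(f"{g}\t{g}\n" for g in genes))
    (path / "barcodes.tsv").write_text("".join(f"{b}\n" for b in barcodes))
    return path
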