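import numpy as np
import pytest

from sumoscreen.arrays import ArrayScan, ArraySpot


def make_spot(
    block=1, row=1, col=1, x=100.0, y=100.0, fid="FEAT00000", pid="PROT00000",
    control=False, fg=1000.0, bg=100.0, bg_sd=10.0, flag=0,
):
    return ArraySpot(
        block_id=block, row=row, col=col, x=x, y=y, feature_id=fid,
        protein_id=pid, is_control=control, fg_median=fg, bg_median=bg,
        bg_sd=bg_sd, flag=flag,
    )


@pytest.fixture
def spot_factory():
    return make_spot


@pytest.fixture
def gpr_text():
    """A 4-row GPR fixture: 2 features in duplicate, plus ATF header."""
    return (
        "ATF\t1.0\n"
        "2\t11\n"
        '"Type=GenePix Results 3"\n'
        '"Scanner=test"\n'
        "Block\tRow\tColumn\tX\tY\tID\tName\tF median\tB median\tB SD\tFlags\n"
        "1\t1\t1\t100\t100\tFEAT00001\tPROT00001\t1000\t100\t10\t0\n"
        "1\t1\t2\t300\t100\tFEAT00001\tPROT00001\t1100\t100\t10\t0\n"
        "1\t2\t1\t100\t300\tFEAT00002\tPROT00002\t500\t100\t10\t0\n"
        "1\t2\t2\t300\t300\tFEAT00002\tPROT00002\t520\t100\t10\t0\n"
    )


@pytest.fixture
def gpr_file(tmp_path, gpr_text):
    path = tmp_path / "scan.gpr"
    path.write_text(gpr_text)
    return path


def scan_from_spots(spots, condition="bound"):
    return ArrayScan(spots=spots, condition=condition)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
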