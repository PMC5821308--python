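import numpy as np
import pytest

from oriscope import OriginCall, OriginSet, ProbeGrid, RatioTrack, make_genome


@pytest.fixture
def small_grid() -> ProbeGrid:
    """One 200-kb chromosome tiled every 250 bp (800 probes)."""
    return make_genome([200_000], 250, names=["chr1"])


@pytest.fixture
def make_track():
    """Factory: RatioTrack on a fresh single-chromosome grid from raw values."""

    def _make(values, valid=None, spacing=250, name="chr1") -> RatioTrack:
        values = np.asarray(values, dtype=float)
        grid = make_genome([spacing * len(values)], spacing, names=[name])
        if valid is None:
            valid = np.ones(len(values), dtype=bool)
        return RatioTrack(
            grid=grid, values={name: values.copy()}, valid={name: np.asarray(valid, bool)}
        )

    return _make


@pytest.fixture
def truth_as_origin_set():
    """Factory: an OriginSet at the true positions/efficiencies of a truth map."""

    def _make(truth, label="truth") -> OriginSet:
        calls = [
            OriginCall(
                chrom=str(r.chrom),
                position=int(r.position),
                copy_number=1.0 + r.efficiency / 100.0,
                efficiency=float(r.efficiency),
            )
            for r in truth.origins.itertuples(index=False)
        ]
        return OriginSet(calls=calls, label=label)

    return _make
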