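import numpy as np
import pytest

from cocoprom.io import FIVE_PRIME, THREE_PRIME, StrandedEndTrack
from cocoprom.peaks import Peak, SiteCall
from cocoprom.io import GenomicInterval


def make_site(position, strand, count=10, chrom="chr1", kind="CTSS",
              with_peak=True, peak_halfwidth=5, peak_total=None):
    """A SiteCall with an optional synthetic source peak around the summit."""
    peak = None
    if with_peak:
        start = max(position - peak_halfwidth, 0)
        end = position + peak_halfwidth + 1
        positions = np.arange(start, end, dtype=np.int64)
        counts = np.ones(positions.size, dtype=np.int64)
        counts[positions == position] = count
        if peak_total is not None:
            # concentrate the requested total in the summit base
            counts[:] = 0
            counts[positions == position] = peak_total
        peak = Peak(GenomicInterval(chrom, start, end, strand), positions, counts)
    site = SiteCall(chrom=chrom, position=position, strand=strand, kind=kind,
                    pooled_count=count, peak=peak)
    if peak is not None:
        peak.summit = site
    return site


def make_end_track(entries, signal_kind=FIVE_PRIME, sample_id="s1"):
    """Track from {(chrom, strand): {position: count}} dicts."""
    track = StrandedEndTrack(sample_id, signal_kind)
    for (chrom, strand), posmap in entries.items():
        pos = np.array(sorted(posmap), dtype=np.int64)
        cnt = np.array([posmap[p] for p in sorted(posmap)], dtype=np.int64)
        track.add_counts(chrom, strand, pos, cnt)
    return track


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
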