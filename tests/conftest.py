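import pytest

from spliceomir.simulate import SimulationSpec, make_annotation_fixture


@pytest.fixture(scope="session")
def small_spec():
    return SimulationSpec(n_mirnas=20, mean_reads_per_mirna=200.0)


@pytest.fixture(scope="session")
def fixture7(small_spec):
    """A shared synthetic annotation fixture (20 hairpins, seed 7)."""
    with pytest.warns(UserWarning):
        return make_annotation_fixture(small_spec, seed=7)


def classify_oracle(read, segment_maps, strand_mode="same"):
    """Independent position-label oracle for read classification.

    Scans every hairpin window; a read is assignable when both its ends lie
    inside the window and the strand matches.  The winning window minimizes
    the read-midpoint-to-window-midpoint distance (ties: smallest id).  The
    category labels every covered position one by one: a single distinct
    label is the category, two or more is overlap.
    """
    candidates = []
    for hid, smap in segment_maps.items():
        w = smap.window
        iv = read.interval
        if w.chrom != iv.chrom or iv.start < w.start or iv.end > w.end:
            continue
        if strand_mode == "same" and w.strand != iv.strand:
            continue
        dist = abs((iv.start + iv.end) - (w.start + w.end))
        candidates.append((dist, hid))
    if not candidates:
        return None, "unassigned"
    candidates.sort()
    hid = candidates[0][1]
    smap = segment_maps[hid]
    ls, le = smap.to_local(read.interval)
    labels = {smap.label_at(pos) for pos in range(ls, le)}
    return hid, labels.pop() if len(labels) == 1 else "overlap"
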