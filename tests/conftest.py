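import numpy as np
import pytest

from preyfield import AnnotationSet, ObjectRecord


def make_record(i, image_id="img0", length=50.0, resolvability="resolvable", subtype="plain"):
    return ObjectRecord(image_id, f"obj{i}", length, resolvability, subtype)


@pytest.fixture
def small_set():
    """Five records over two images: one partial and one packed aggregation."""
    return AnnotationSet(
        (
            make_record(0, "a", 72.0),
            make_record(1, "a", 40.0, subtype="partial"),
            make_record(2, "a", 15.0, resolvability="unresolvable"),
            make_record(3, "b", 55.0, subtype="packed_aggregation"),
            make_record(4, "b", 33.0, resolvability="unresolvable"),
        )
    )


@pytest.fixture(scope="session")
def reported_class_totals_set():
    """An annotation set reproducing the reported resolvability-class totals.

    3,079 plain + 154 bent + 193 partial + 12 axial + 125 motion-blurred
    resolvable records and 1,474 unresolvable objects, spread over 124
    images round-robin.  Lengths are arbitrary positive values; only the
    class composition matters to counting operations.
    """
    totals = [
        ("resolvable", "plain", 3079),
        ("resolvable", "bent", 154),
        ("resolvable", "partial", 193),
        ("resolvable", "axial", 12),
        ("resolvable", "motion_blurred", 125),
        ("unresolvable", "plain", 1474),
    ]
    rng = np.random.default_rng(12345)
    records = []
    i = 0
    for resolvability, subtype, n in totals:
        for _ in range(n):
            records.append(
                ObjectRecord(
                    image_id=f"img{i % 124:03d}",
                    object_id=f"o{i}",
                    imaged_length_px=float(rng.uniform(10, 200)),
                    resolvability=resolvability,
                    subtype=subtype,
                )
            )
            i += 1
    return AnnotationSet(tuple(records))
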