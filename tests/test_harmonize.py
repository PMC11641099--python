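"""Detector intersection, count attachment and known/novel flagging."""

import numpy as np
import pandas as pd
import pytest

from circrpl import io_formats as iof
from circrpl.harmonize import attach_counts, flag_known, intersect_calls
from circrpl.io_formats import BSJKey, CircCall, CountMatrix, MetadataError


def make_calls(keys, detector, sample="s1", count=1):
    return [CircCall(k, detector, {sample: count}) for k in keys]


def random_keys(rng, n, chroms=("chr1", "chr2")):
    out = set()
    while len(out) < n:
        s = int(rng.integers(1, 100_000))
        out.add(
            BSJKey(
                str(rng.choice(chroms)),
                s,
                s + int(rng.integers(1, 2000)),
                str(rng.choice(["+", "-"])),
            )
        )
    return out


class TestIntersect:
    def test_disjoint_sets_empty(self):
        a = make_calls({BSJKey("chr1", 1, 10, "+")}, "DCC")
        b = make_calls({BSJKey("chr1", 20, 30, "+")}, "CIRI2")
        assert intersect_calls(a, b).records == {}

    def test_identical_sets_identity(self):
        keys = {BSJKey("chr1", i * 100, i * 100 + 50, "+") for i in range(1, 11)}
        cons = intersect_calls(make_calls(keys, "DCC"), make_calls(keys, "CIRI2"))
        assert set(cons.records) == keys

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(7)
        a_keys = list(random_keys(rng, 300))
        b_keys = list(random_keys(rng, 300))
        # plant a known overlap
        b_keys[:100] = a_keys[:100]
        cons = intersect_calls(make_calls(a_keys, "DCC"), make_calls(b_keys, "CIRI2"))
        brute = {ka for ka in a_keys for kb in b_keys if ka == kb}
        assert set(cons.records) == brute

    def test_commutative_and_idempotent(self):
        rng = np.random.default_rng(8)
        a = make_calls(random_keys(rng, 50), "DCC")
        b = make_calls(random_keys(rng, 50), "CIRI2")
        ab = set(intersect_calls(a, b).records)
        ba = set(intersect_calls(b, a).records)
        assert ab == ba
        aa = set(intersect_calls(a, a).records)
        assert aa == {c.key for c in a}

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        a = make_calls(random_keys(rng, 60), "DCC")
        b = make_calls(random_keys(rng, 60), "CIRI2")
        ref = set(intersect_calls(a, b).records)
        assert set(intersect_calls(a[::-1], b[::-1]).records) == ref

    def test_strand_flag(self):
        plus = BSJKey("chr1", 100, 200, "+")
        minus = BSJKey("chr1", 100, 200, "-")
        a, b = make_calls({plus}, "DCC"), make_calls({minus}, "CIRI2")
        assert intersect_calls(a, b, match_strand=True).records == {}
        cons = intersect_calls(a, b, match_strand=False)
        # conflicting strands resolve to '.'
        assert list(cons.records) == [BSJKey("chr1", 100, 200, ".")]

    def test_duplicates_within_detector_collapse_to_max(self):
        k = BSJKey("chr1", 1, 10, "+")
        a = [CircCall(k, "DCC", {"s1": 3}), CircCall(k, "DCC", {"s1": 9})]
        b = make_calls({k}, "CIRI2")
        with pytest.warns(UserWarning):
            cons = intersect_calls(a, b)
        assert cons.provenance[k]["DCC"] == {"s1": 9}


def small_count_matrix(keys, samples=("s1", "s2", "s3"), values=(5, 0, 7)):
    sheet = pd.DataFrame(
        {
            "project_id": ["P1"] * len(samples),
            "condition": ["control", "RPL", "RPL"][: len(samples)],
            "library_size": [10_000_000] * len(samples),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    counts = pd.DataFrame(
        [list(values)] * len(keys), index=[k.id() for k in keys], columns=samples
    )
    return CountMatrix(counts, sheet)


class TestAttachCounts:
    def test_exact_attachment(self):
        k = BSJKey("chr1", 1, 10, "+")
        cons = intersect_calls(make_calls({k}, "DCC"), make_calls({k}, "CIRI2"))
        attach_counts(cons, small_count_matrix([k]))
        assert cons.records[k] == {"s1": 5, "s2": 0, "s3": 7}

    def test_missing_bsj_gets_zeros(self, caplog):
        k = BSJKey("chr1", 1, 10, "+")
        other = BSJKey("chr2", 1, 10, "+")
        cons = intersect_calls(make_calls({k}, "DCC"), make_calls({k}, "CIRI2"))
        import logging

        with caplog.at_level(logging.WARNING, logger="circrpl.harmonize"):
            attach_counts(cons, small_count_matrix([other]))
        assert cons.records[k] == {"s1": 0, "s2": 0, "s3": 0}
        assert any("missing from quantification" in r.message for r in caplog.records)

    def test_row_order_permutation_invariance(self):
        rng = np.random.default_rng(10)
        keys = sorted(random_keys(rng, 20))
        cons1 = intersect_calls(make_calls(keys, "DCC"), make_calls(keys, "CIRI2"))
        cons2 = intersect_calls(make_calls(keys, "DCC"), make_calls(keys, "CIRI2"))
        cm = small_count_matrix(keys)
        shuffled = CountMatrix(cm.counts.sample(frac=1, random_state=1), cm.samples)
        attach_counts(cons1, cm)
        attach_counts(cons2, shuffled)
        assert cons1.records == cons2.records

    def test_unknown_sample_in_counts_is_error(self):
        k = BSJKey("chr1", 1, 10, "+")
        cm = small_count_matrix([k])
        bad = cm.counts.copy()
        bad["ghost"] = 1
        with pytest.raises(MetadataError):
            CountMatrix(bad, cm.samples)


class TestFlagKnown:
    def test_empty_catalogue_all_novel(self):
        k = BSJKey("chr1", 1, 10, "+")
        cons = intersect_calls(make_calls({k}, "DCC"), make_calls({k}, "CIRI2"))
        assert flag_known(cons, set()) == {k: False}

    def test_superset_catalogue_all_known(self):
        rng = np.random.default_rng(11)
        keys = random_keys(rng, 30)
        cons = intersect_calls(make_calls(keys, "DCC"), make_calls(keys, "CIRI2"))
        flags = flag_known(cons, keys | random_keys(rng, 10))
        assert all(flags.values())

    def test_planted_known_flags_match_truth(self, clean_bundle):
        b = clean_bundle
        pid = b.project_ids()[0]
        dcc = iof.read_dcc_calls(*b.paths["dcc"][pid])
        ciri = []
        for sp in b.paths["ciri"][pid]:
            ciri.extend(iof.read_ciri2_calls(sp))
        cons = intersect_calls(dcc, ciri, project_id=pid)
        flags = flag_known(cons, iof.read_catalogue(b.paths["known_catalogue"]))
        truth = {c.key: c.known for c in b.circs}
        assert flags == truth
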