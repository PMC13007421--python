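"""Binding-site search, product prediction and the end-point yield model."""

import pytest
from hypothesis import given, strategies as st

from gmoscreen.insilico_pcr import (
    AmplificationModel, Template, find_binding_sites, predict_products,
    revcomp, run_multiplex,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def _toy_template(seq, topology="linear", conc=30.0):
    return Template(name="toy", seq=seq, topology=topology, conc_ng_per_ul=conc)


class TestRevcomp:
    def test_examples(self):
        assert revcomp("ACGT") == "ACGT"
        assert revcomp("AAAC") == "GTTT"

    @given(dna)
    def test_involution(self, seq):
        assert revcomp(revcomp(seq)) == seq

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            revcomp("ACGN")


class TestBindingSites:
    def test_verbatim_primer_found_once(self, soy_panel):
        fwd = soy_panel.assays["pat"].fwd
        t = _toy_template("GG" * 20 + fwd + "CC" * 20)
        sites = find_binding_sites(t, fwd)
        assert len(sites) == 1
        assert (sites[0].strand, sites[0].start, sites[0].mismatches) == ("+", 40, 0)

    def test_no_complement_no_site(self):
        t = _toy_template("A" * 200)
        assert find_binding_sites(t, "TGCATGCATGCA") == []

    def test_reverse_strand_site(self):
        primer = "TGCATCGATCGA"
        t = _toy_template("AAA" + revcomp(primer) + "TTT")
        sites = find_binding_sites(t, primer)
        assert len(sites) == 1 and sites[0].strand == "-"
        assert (sites[0].start, sites[0].end) == (3, 15)

    def test_protected_3prime_blocks_terminal_mismatch(self):
        primer = "TGCATCGATCGATTTCCGGA"
        # mismatch at the last base: blocked even with max_mismatch=1
        site = primer[:-1] + "C"
        t = _toy_template("GG" * 10 + site + "CC" * 10)
        assert find_binding_sites(t, primer, max_mismatch=1) == []
        # same single mismatch at the 5' end: tolerated
        site5 = "A" + primer[1:]
        t5 = _toy_template("GG" * 10 + site5 + "CC" * 10)
        sites = find_binding_sites(t5, primer, max_mismatch=1)
        assert len(sites) == 1 and sites[0].mismatches == 1

    def test_origin_spanning_site_matches_rotation_oracle(self):
        primer = "TGCATCGATCGATTTCCGGA"
        core = "A" * 90 + "C" * 90  # 180 nt, primer-free
        # place the primer across the origin: last 8 nt at the end, rest at start
        seq = primer[8:] + core + primer[:8]
        t = _toy_template(seq, topology="circular")
        sites = find_binding_sites(t, primer)
        assert len(sites) == 1
        assert sites[0].start == len(seq) - 8 and sites[0].end == len(seq) + 12
        # oracle: scanning every rotation must find exactly one + site
        for rot in range(0, len(seq), 25):
            rotated = _toy_template(seq[rot:] + seq[:rot], topology="circular")
            rsites = find_binding_sites(rotated, primer)
            assert len(rsites) == 1
            assert rsites[0].start % len(seq) == (sites[0].start - rot) % len(seq)

    def test_fewer_mismatches_never_more_sites(self):
        primer = "ACGTTGCAACGTTGCAACGT"
        t = _toy_template("ACGTTGCAACGTAGCAACGT" * 5 + "T" * 30)
        n = [len(find_binding_sites(t, primer, max_mismatch=m)) for m in (0, 1, 2)]
        assert n == sorted(n)


def _brute_force_products(template, assay, max_len=500):
    """Independent O(n²) oracle: enumerate all site pairs by regex-free scan."""
    seq = template.seq
    L = len(seq)
    circular = template.topology == "circular"
    probe = seq + (seq if circular else "")

    def occurrences(pat):
        out, pos = [], probe.find(pat)
        while pos != -1:
            if pos < L:
                out.append(pos)
            pos = probe.find(pat, pos + 1)
        return out

    products = set()
    for left, right in (
        (assay.fwd, revcomp(assay.rev)),
        (assay.rev, revcomp(assay.fwd)),
    ):
        for i in occurrences(left):
            for j in occurrences(right):
                jj = j if j >= i else (j + L if circular else None)
                if jj is None or jj < i + len(left):
                    continue
                length = jj + len(right) - i
                if len(assay.fwd) + len(assay.rev) <= length <= max_len:
                    products.add((i, length))
    return products


class TestPredictProducts:
    def test_pat_synthetic_insert_is_93bp(self, soy_panel):
        pat = soy_panel.assays["pat"]
        seq = pat.fwd + "G" * 50 + revcomp(pat.rev)
        amps = predict_products(_toy_template(seq), pat)
        assert [a.length_bp for a in amps] == [93]
        assert (amps[0].start, amps[0].end) == (0, 93)

    def test_no_reverse_site_no_product(self, soy_panel):
        pat = soy_panel.assays["pat"]
        amps = predict_products(_toy_template(pat.fwd + "G" * 100), pat)
        assert amps == []

    def test_multiple_forward_sites_match_pair_oracle(self, soy_panel):
        pat = soy_panel.assays["pat"]
        seq = pat.fwd + "G" * 30 + pat.fwd + "C" * 40 + revcomp(pat.rev)
        t = _toy_template(seq)
        amps = predict_products(t, pat)
        assert len(amps) == 2
        assert {(a.start, a.length_bp) for a in amps} == _brute_force_products(t, pat)

    @pytest.mark.parametrize("topology", ["linear", "circular"])
    def test_matches_oracle_on_both_orientations(self, soy_panel, topology):
        pat = soy_panel.assays["pat"]
        # one forward-orientation insert and one flipped insert
        insert = pat.fwd + "G" * 50 + revcomp(pat.rev)
        seq = "A" * 40 + insert + "C" * 60 + revcomp(insert) + "T" * 40
        t = _toy_template(seq, topology=topology)
        amps = predict_products(t, pat)
        assert {(a.start % len(seq), a.length_bp) for a in amps} == \
            _brute_force_products(t, pat)

    def test_strand_symmetry(self, soy_panel):
        pat = soy_panel.assays["pat"]
        seq = "A" * 37 + pat.fwd + "G" * 50 + revcomp(pat.rev) + "C" * 23
        t = _toy_template(seq)
        rc = _toy_template(revcomp(seq))
        fw = {(a.start, a.end) for a in predict_products(t, pat)}
        bw = {(len(seq) - e, len(seq) - s) for a in predict_products(rc, pat)
              for s, e in [(a.start, a.end)]}
        assert fw == bw

    def test_rotation_invariance_of_circular_products(self, soy_panel, soy_plasmid):
        pat = soy_panel.assays["pat"]
        base = sorted(a.length_bp for a in predict_products(soy_plasmid, pat))
        seq = soy_plasmid.seq
        for rot in (1, 137, len(seq) // 2):
            rotated = Template(name="rot", seq=seq[rot:] + seq[:rot],
                               topology="circular", conc_ng_per_ul=30.0)
            lens = sorted(a.length_bp for a in predict_products(rotated, pat))
            assert lens == base

    def test_shorter_max_product_len_never_more_products(self, soy_panel, soy_plasmid):
        counts = [
            len(predict_products(soy_plasmid, soy_panel.assays["T-E9"],
                                 max_product_len=m))
            for m in (100, 250, 500)
        ]
        assert counts == sorted(counts)


class TestMultiplex:
    def test_soyI_on_plasmid(self, soy_panel, soy_plasmid):
        amps = run_multiplex(soy_plasmid, soy_panel.sets[0], soy_panel)
        assert [a.length_bp for a in amps] == [93, 148, 223]
        assert all(a.yield_ng_per_ul > 0 for a in amps)

    def test_zero_concentration_yields_nothing(self, soy_panel, soy_plasmid):
        cold = Template(name="cold", seq=soy_plasmid.seq, topology="circular",
                        conc_ng_per_ul=0.0)
        assert run_multiplex(cold, soy_panel.sets[0], soy_panel) == []

    def test_unknown_assay_in_set_is_error(self, soy_panel, maize_panel, soy_plasmid):
        with pytest.raises(KeyError):
            run_multiplex(soy_plasmid, maize_panel.sets[0], soy_panel)

    def test_yield_increases_with_concentration_below_saturation(self):
        model = AmplificationModel()
        concs = [1e-4, 3e-4, 1e-3]
        ys = [model.endpoint_yield(c, "pat", 32) for c in concs]
        assert ys == sorted(ys) and len(set(ys)) == 3
        assert all(y < model.saturation_ng_per_ul for y in ys)

    def test_reduced_efficiency_lowers_subsaturation_yield(self):
        model = AmplificationModel()
        strong = model.endpoint_yield(1e-4, "pat", 240)
        weak = model.endpoint_yield(1e-4, "DMO", 240)
        assert weak < strong
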