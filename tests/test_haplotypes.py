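import numpy as np
import pytest

from beetol import haplotypes as hp
from beetol import simulate


class TestTranslate:
    def test_simple_orf(self):
        out = hp.translate_cds("ATGGAATAA")
        assert out.protein == "ME"
        assert out.premature_stop is False

    def test_premature_stop_flagged(self):
        out = hp.translate_cds("ATGTAAGAA")
        assert out.protein == "M"
        assert out.premature_stop is True

    def test_gaps_removed_before_translation(self):
        assert hp.translate_cds("ATG---GAATAA").protein == "ME"

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            hp.translate_cds("ATGGA")

    def test_ambiguous_codon_is_x_with_warning(self):
        with pytest.warns(UserWarning, match="ambiguous"):
            out = hp.translate_cds("ATGNNNTAA")
        assert out.protein == "MX"


class TestParseChange:
    @pytest.mark.parametrize(
        "label,pos,ref,alt",
        [("Gln60Glu", 60, "Q", "E"), ("Thr302del", 302, "T", "-"),
         ("Ser300Ter", 300, "S", "*")],
    )
    def test_round_trip(self, label, pos, ref, alt):
        ev = hp.parse_change(label)
        assert (ev.position, ev.ref, ev.alt) == (pos, ref, alt)
        assert ev.label == label

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            hp.parse_change("60Q>E")


class TestCallChanges:
    ref = simulate.reference_for_profiles(
        120, {"x": ("Gln60Glu", "Thr62Met", "Thr100del")}, seed=5
    )

    def test_identical_sequence_is_wildtype(self):
        prof = hp.call_changes(self.ref, self.ref, gene="g")
        assert prof.is_wildtype

    def test_substitutions_called_at_right_positions(self):
        sample = simulate.simulate_cds_set(
            self.ref, {"s": ("Gln60Glu", "Thr62Met")}
        )["s"]
        prof = hp.call_changes(sample, self.ref, gene="g")
        assert prof.key == ("Gln60Glu", "Thr62Met")

    def test_inframe_deletion_called(self):
        sample = simulate.simulate_cds_set(self.ref, {"d": ("Thr100del",)})["d"]
        prof = hp.call_changes(sample, self.ref)
        assert prof.key == ("Thr100del",)
        assert not prof.truncated

    def test_truncation_ends_comparison(self):
        sample = simulate.simulate_cds_set(
            self.ref, {"t": ("Gln60Glu", "Thr62Met")}
        )["t"]
        # plant a premature stop between the two substitutions
        trunc = simulate.simulate_cds_set(self.ref, {"t": ("Gln60Glu",)})["t"]
        stop = list(trunc)
        stop[61 * 3 - 3 : 61 * 3] = "TAA"
        prof = hp.call_changes("".join(stop), self.ref)
        assert prof.events[-1].alt == "*"
        assert prof.truncated
        # nothing after the stop is reported
        assert all(e.position <= 61 for e in prof.events)

    def test_frameshifting_gap_names_column(self):
        sample = list(self.ref)
        sample[30] = "-"
        with pytest.raises(ValueError, match="column 31"):
            hp.call_changes("".join(sample), self.ref)

    def test_cds_offset_window_positions_match_full_protein(self):
        # sequenced window starting at CDS nt 100 (phase 0 after skip)
        window = self.ref[99:]
        sample = simulate.simulate_cds_set(self.ref, {"s": ("Thr62Met",)})["s"][99:]
        prof = hp.call_changes(sample, self.ref, cds_offset=100)
        assert prof.key == ("Thr62Met",)


class TestCatalog:
    def _profiles(self, labels_by_worker):
        out = {}
        for w, (g1, g3) in labels_by_worker.items():
            out[w] = {
                "CYP9Q1": hp.ChangeProfile(
                    "CYP9Q1", tuple(hp.parse_change(l) for l in g1)
                ),
                "CYP9Q3": hp.ChangeProfile(
                    "CYP9Q3", tuple(hp.parse_change(l) for l in g3)
                ),
            }
        return out

    def test_all_wildtype_single_combination(self):
        profs = self._profiles({f"w{i}": ((), ()) for i in range(5)})
        cat = hp.build_catalog(profs, genes=("CYP9Q1", "CYP9Q3"))
        assert cat.n_combinations == 1
        assert set(cat.combos.values()) == {"wt|wt"}

    def test_shared_nonempty_profile_shares_label(self):
        profs = self._profiles(
            {"w0": ((), ()), "w1": (("Gln60Glu",), ()), "w2": (("Gln60Glu",), ())}
        )
        cat = hp.build_catalog(profs, genes=("CYP9Q1", "CYP9Q3"))
        labels = {w: v["CYP9Q1"] for w, v in cat.sample_labels.items()}
        assert labels["w1"] == labels["w2"] == "A"
        assert labels["w0"] == "wt"

    def test_labels_invariant_to_input_order(self):
        base = {
            "w0": (("Gln60Glu",), ("Thr62Met",)),
            "w1": (("Pro87Ser",), ()),
            "w2": (("Gln60Glu",), ()),
            "w3": ((), ("Thr62Met", "Thr152Ile")),
        }
        profs = self._profiles(base)
        reversed_profs = dict(reversed(list(profs.items())))
        a = hp.build_catalog(profs, genes=("CYP9Q1", "CYP9Q3"))
        b = hp.build_catalog(reversed_profs, genes=("CYP9Q1", "CYP9Q3"))
        assert a.labels == b.labels
        assert a.combos == b.combos

    def test_distinct_combination_count_matches_truth(self, rng):
        """Mixing gene-level profiles across simulated drones: the catalog
        recovers exactly the planted number of distinct combinations."""
        genes = list(simulate.GENES)
        refs = {
            g: simulate.reference_for_profiles(
                520, simulate.DEFAULT_GENE_PROFILES[g], seed=i
            )
            for i, g in enumerate(genes)
        }
        cds = {
            g: simulate.simulate_cds_set(refs[g], simulate.DEFAULT_GENE_PROFILES[g])
            for g in genes
        }
        workers = {}
        planted = set()
        for i in range(40):
            combo = tuple(
                rng.choice(sorted(simulate.DEFAULT_GENE_PROFILES[g])) for g in genes
            )
            planted.add(combo)
            workers[f"w{i}"] = {
                g: hp.call_changes(cds[g][lab], refs[g], gene=g)
                for g, lab in zip(genes, combo)
            }
        cat = hp.build_catalog(workers, genes=genes)
        assert cat.n_combinations == len(planted)

    def test_user_label_map_overrides(self):
        profs = self._profiles({"w0": (("Gln60Glu",), ())})
        cat = hp.build_catalog(
            profs,
            genes=("CYP9Q1", "CYP9Q3"),
            label_map={"CYP9Q1": {("Gln60Glu",): "Z"}},
        )
        assert cat.sample_labels["w0"]["CYP9Q1"] == "Z"
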