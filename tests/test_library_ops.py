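"""Library algebra: predicted-library construction, hybrid precedence,
focused subsetting, decoys, entrapment, calibration and TSV round trips."""

import numpy as np
import pandas as pd
import pytest

from phosphodia import library_ops as lo
from phosphodia import neural_model as nm
from phosphodia import synthetic_data as sd
from phosphodia.ion_space import IonChannel, Peak, fragment_mz, precursor_mz, validity_mask
from phosphodia.peptide_codec import (
    PHOSPHO,
    OXIDATION,
    Precursor,
    format_compact,
    parse_compact,
)
from conftest import random_peptide


def toy_entry(text, charge=2, irt=10.0, source="predicted", species=""):
    pep = parse_compact(text, min_len=4)
    ch = IonChannel("y", 1, "noloss")
    peaks = (Peak(ch, 2, fragment_mz(pep, ch, 2), 1.0),)
    return lo.LibraryEntry(
        precursor=Precursor(pep, charge),
        precursor_mz=precursor_mz(Precursor(pep, charge)),
        irt=irt,
        peaks=peaks,
        source=source,
        species=species,
    )


def toy_library(texts, source="predicted", **kw):
    return lo.SpectralLibrary([toy_entry(t, source=source, **kw) for t in texts])


@pytest.fixture(scope="module")
def predicted_library(trained_models, tiny_corpus):
    ion_model, rt_ens, _, _ = trained_models
    _, precursors, _, _, _ = tiny_corpus
    filters = lo.LibraryFilters(intensity_floor=0.02)
    return lo.generate_predicted_library(precursors, ion_model, rt_ens, filters)


class TestPredictedLibrary:
    def test_fragment_mz_window_enforced(self, predicted_library):
        lo_mz, hi_mz = predicted_library.filters.fragment_mz_range
        for e in predicted_library:
            for pk in e.peaks:
                assert lo_mz <= pk.mz <= hi_mz

    def test_top_n_cap(self, predicted_library):
        cap = predicted_library.filters.top_n_fragments
        assert all(len(e.peaks) <= cap for e in predicted_library)

    def test_entry_count_bounded_by_precursors(self, predicted_library, tiny_corpus):
        _, precursors, _, _, _ = tiny_corpus
        assert 0 < len(predicted_library) <= len(precursors)

    def test_precursor_filters_drop(self, trained_models, tiny_corpus):
        ion_model, rt_ens, _, _ = trained_models
        _, precursors, _, _, _ = tiny_corpus
        filters = lo.LibraryFilters(charges=(2,))
        lib = lo.generate_predicted_library(precursors, ion_model, rt_ens, filters)
        n2 = sum(1 for pr in precursors if pr.charge == 2)
        assert lib.dropped == len(precursors) - n2
        assert all(e.precursor.charge == 2 for e in lib)

    def test_filter_monotonicity(self, trained_models, tiny_corpus):
        """Tightening any bound never increases entries or peaks."""
        ion_model, rt_ens, _, _ = trained_models
        _, precursors, _, _, _ = tiny_corpus
        loose = lo.generate_predicted_library(
            precursors, ion_model, rt_ens, lo.LibraryFilters(intensity_floor=0.01)
        )
        for tighter in (
            lo.LibraryFilters(intensity_floor=0.2),
            lo.LibraryFilters(intensity_floor=0.01, fragment_mz_range=(300, 900)),
            lo.LibraryFilters(intensity_floor=0.01, peptide_length_range=(7, 10)),
            lo.LibraryFilters(intensity_floor=0.01, top_n_fragments=5),
            lo.LibraryFilters(intensity_floor=0.01, charges=(2,)),
        ):
            tight = lo.generate_predicted_library(precursors, ion_model, rt_ens, tighter)
            assert len(tight) <= len(loose)
            assert tight.n_peaks() <= loose.n_peaks()


class TestCalibration:
    def test_exact_line_recovered(self):
        from dataclasses import replace

        lib = toy_library([f"@AGLDET{aa}K" for aa in "SVILFW"])
        for i, e in enumerate(list(lib)):
            lib.entries[e.key] = replace(e, irt=float(i))
        pairs = {e.key: 2.0 * e.irt + 10.0 for e in lib}
        fit, calibrated = lo.calibrate_irt(lib, pairs)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(10.0)
        assert fit.r2 == pytest.approx(1.0)
        for e in calibrated:
            assert e.irt == pytest.approx(pairs[e.key])

    def test_identity_pairs(self):
        lib = lo.SpectralLibrary(
            [toy_entry(f"@AGLDET{aa}K", irt=float(i)) for i, aa in enumerate("SVI")]
        )
        pairs = {e.key: e.irt for e in lib}
        fit, _ = lo.calibrate_irt(lib, pairs)
        assert (fit.slope, fit.intercept) == (pytest.approx(1.0), pytest.approx(0.0, abs=1e-9))

    def test_noisy_line_recovery(self):
        rng = np.random.default_rng(0)
        texts = []
        while len(texts) < 100:
            t = format_compact(random_peptide(rng, 7, 12))
            if t not in texts:
                texts.append(t)
        lib = lo.SpectralLibrary(
            [toy_entry(t, irt=float(rng.uniform(0, 100))) for t in texts]
        )
        pairs = {e.key: 1.7 * e.irt - 4.0 + rng.normal(0, 1.0) for e in lib}
        fit, _ = lo.calibrate_irt(lib, pairs)
        assert fit.slope == pytest.approx(1.7, abs=0.05)
        assert fit.intercept == pytest.approx(-4.0, abs=3.0)

    def test_too_few_pairs(self):
        lib = toy_library(["@AGLDETSK"])
        with pytest.raises(ValueError, match=">=3"):
            lo.calibrate_irt(lib, {e.key: 1.0 for e in lib})


class TestHybridMerge:
    def test_disjoint_union(self):
        a = toy_library(["@AAADETSK", "@CCCDETSK"], source="direct_DIA")
        b = toy_library(["@DDDDETSK", "@EEEDETSK", "@FFFDETSK"])
        assert len(lo.merge_hybrid(a, b)) == 5

    def test_experimental_precedence_and_idempotence(self):
        shared = "@AAADETSK"
        a = lo.SpectralLibrary([toy_entry(shared, irt=1.0, source="direct_DIA")])
        b = lo.SpectralLibrary([toy_entry(shared, irt=99.0), toy_entry("@CCCDETSK")])
        merged = lo.merge_hybrid(a, b)
        key = (shared, 2)
        assert merged.get(key).source == "direct_DIA"
        assert merged.get(key).irt == 1.0
        again = lo.merge_hybrid(merged, b)
        assert set(again.keys()) == set(merged.keys())
        assert again.get(key).irt == 1.0

    def test_inputs_not_mutated(self):
        a = toy_library(["@AAADETSK"], source="direct_DIA")
        b = toy_library(["@CCCDETSK"])
        na, nb = len(a), len(b)
        lo.merge_hybrid(a, b)
        assert len(a) == na and len(b) == nb


class TestFocused:
    def test_pure_predicted_subsetting(self):
        lib = toy_library([f"@AG{aa}DETSK" for aa in "LVIFWY"])
        keys = list(lib.keys())[:2]
        out = lo.build_focused(lib, keys)
        assert set(out.keys()) == set(keys)

    def test_hybrid_keeps_experimental_whole(self):
        exp = toy_library(["@AAADETSK", "@CCCDETSK"], source="direct_DIA")
        pred = toy_library([f"@AG{aa}DETSK" for aa in "LVIFW"])
        hybrid = lo.merge_hybrid(exp, pred)
        identified = list(pred.keys())[:2]
        out = lo.build_focused(hybrid, identified, keep_experimental_whole=True)
        assert len(out) == 2 + 2
        out2 = lo.build_focused(hybrid, identified, keep_experimental_whole=False)
        assert set(out2.keys()) == set(identified)

    def test_never_larger_and_unknown_keys_logged(self):
        lib = toy_library([f"@AG{aa}DETSK" for aa in "LVIF"])
        out = lo.build_focused(lib, list(lib.keys()) + [("@ZZZ", 2)])
        assert len(out) <= len(lib)
        assert out.unknown_keys == [("@ZZZ", 2)]

    def test_empty_result_rejected(self):
        lib = toy_library(["@AGLDETSK"])
        with pytest.raises(ValueError):
            lo.build_focused(lib, [("@NOPE", 2)], keep_experimental_whole=False)


class TestReversePeptide:
    def test_plain_example(self):
        p = parse_compact("@ASDEFK", min_len=4)
        assert lo.reverse_peptide(p).residues == "FEDSAK"

    def test_mods_travel_with_residues(self):
        p = parse_compact("@A2DK", min_len=4)  # A pS D K
        r = lo.reverse_peptide(p)
        assert format_compact(r) == "@D2AK"

    def test_exhaustive_properties(self):
        """C terminus fixed, composition preserved, mods travel, involution."""
        rng = np.random.default_rng(8)
        for _ in range(1000):
            p = random_peptide(rng, 7, 20)
            r = lo.reverse_peptide(p)
            assert r.residues[-1] == p.residues[-1]
            assert sorted(r.residues) == sorted(p.residues)
            assert r.nterm_acetyl == p.nterm_acetyl
            assert sorted(r.mods.values()) == sorted(p.mods.values())
            for pos, kind in r.mods.items():
                assert (r.residues[pos - 1] in "STY") == (kind == PHOSPHO)
            assert lo.reverse_peptide(r) == p

    def test_too_short(self):
        from phosphodia.peptide_codec import ModifiedPeptide

        with pytest.raises(ValueError):
            lo.reverse_peptide(ModifiedPeptide("K"))


class TestDecoyLibrary:
    def test_decoy_append_counts_and_charges(self, predicted_library, trained_models):
        ion_model, rt_ens, _, _ = trained_models
        combined = lo.build_decoy_appended_library(predicted_library, ion_model, rt_ens)
        decoys = [e for e in combined if e.source == "decoy"]
        targets = [e for e in combined if e.source != "decoy"]
        assert len(targets) == len(predicted_library)
        assert 0 < len(decoys) <= len(targets)
        target_charges = {
            format_compact(lo.reverse_peptide(e.precursor.peptide)): e.precursor.charge
            for e in targets
        }
        for d in decoys:
            seq = format_compact(d.precursor.peptide)
            assert target_charges.get(seq) == d.precursor.charge

    def test_palindrome_dropped(self, trained_models):
        ion_model, rt_ens, _, _ = trained_models
        lib = toy_library(["@AADSDAAK"])  # reversal of first n-1 is itself
        combined = lo.build_decoy_appended_library(lib, ion_model, rt_ens)
        assert combined.palindromic_dropped == 1
        assert len(combined) == 1


class TestEntrapment:
    def test_disjoint_sizes(self):
        a = toy_library(["@AAADETSK", "@CCCDETSK"], source="direct_DIA")
        b = toy_library(["@DDDDETSK", "@EEEDETSK", "@FFFDETSK"])
        lib, sizes = lo.build_entrapment_library(a, b, "human", "arabidopsis")
        assert len(lib) == 5
        assert sizes["human"] == 2 and sizes["arabidopsis"] == 3
        assert sizes["overlap_dropped"] == 0

    def test_overlaps_dropped_from_entrapment_side(self):
        a = toy_library(["@AAADETSK", "@CCCDETSK"], source="direct_DIA")
        b = toy_library(["@AAADETSK", "@FFFDETSK"])
        lib, sizes = lo.build_entrapment_library(a, b, "human", "arabidopsis")
        assert sizes == {"human": 2, "arabidopsis": 1, "overlap_dropped": 1}
        # size metadata equals a recount from the merged library
        assert sizes["human"] == len(
            {k[0] for k, e in lib.entries.items() if e.species == "human"}
        )

    def test_same_species_rejected(self):
        a, b = toy_library(["@AAADETSK"]), toy_library(["@CCCDETSK"])
        with pytest.raises(ValueError):
            lo.build_entrapment_library(a, b, "x", "x")


class TestParameterGrid:
    def test_combination_count_and_monotonicity(self, trained_models, tiny_corpus):
        ion_model, rt_ens, _, _ = trained_models
        _, precursors, _, _, _ = tiny_corpus
        grid = {
            "peptide_length_range": [(7, 30), (7, 12), (7, 10)],
            "intensity_floor": [0.01, 0.1],
            "top_n_fragments": [25, 6],
        }
        # mirrors the published screening structure: 3 x 7 combos = 21 libraries
        summary = lo.screen_parameter_grid(precursors, grid, ion_model, rt_ens)
        assert len(summary) == 12
        wide = summary[summary["peptide_length_range"] == (7, 30)]
        narrow = summary[summary["peptide_length_range"] == (7, 10)]
        assert narrow["n_entries"].sum() <= wide["n_entries"].sum()

    def test_empty_grid_rejected(self, trained_models):
        ion_model, rt_ens, _, _ = trained_models
        with pytest.raises(ValueError):
            lo.screen_parameter_grid([], {}, ion_model, rt_ens)


class TestTsvRoundTrip:
    def test_row_count(self, tmp_path):
        lib = toy_library(["@AAADETSK", "@CCCDETSK"])
        path = tmp_path / "lib.tsv"
        lo.write_library_tsv(lib, path)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == lo.TSV_COLUMNS
        assert len(df) == lib.n_peaks()

    def test_roundtrip_identity(self, predicted_library, tmp_path):
        path = tmp_path / "lib.tsv"
        lo.write_library_tsv(predicted_library, path)
        back = lo.read_library_tsv(path)
        assert set(back.keys()) == set(predicted_library.keys())
        for key in predicted_library.keys():
            a, b = predicted_library.get(key), back.get(key)
            assert b.precursor_mz == pytest.approx(a.precursor_mz, abs=1e-4)
            assert b.irt == pytest.approx(a.irt, abs=1e-4)
            assert len(a.peaks) == len(b.peaks)
            for pa, pb in zip(a.peaks, b.peaks):
                assert (pa.channel, pa.fragment_number) == (pb.channel, pb.fragment_number)
                assert pb.intensity == pytest.approx(pa.intensity, abs=1e-4)

    def test_impossible_loss_annotation_rejected(self, tmp_path):
        lib = toy_library(["@AAADETSK"])
        path = tmp_path / "lib.tsv"
        lo.write_library_tsv(lib, path)
        df = pd.read_csv(path, sep="\t")
        df.loc[0, "FragmentLossType"] = "H3PO4"
        df.loc[0, "FragmentNumber"] = 2  # y2 = 'SK'... contains S but unphosphorylated
        df.loc[0, "ModifiedPeptide"] = "_AAADETSK_"  # strip the phospho
        bad = tmp_path / "bad.tsv"
        df.to_csv(bad, sep="\t", index=False)
        with pytest.raises(ValueError, match="impossible"):
            lo.read_library_tsv(bad)

    def test_missing_column_rejected(self, tmp_path):
        lib = toy_library(["@AAADETSK"])
        path = tmp_path / "lib.tsv"
        lo.write_library_tsv(lib, path)
        df = pd.read_csv(path, sep="\t").drop(columns=["iRT"])
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing"):
            lo.read_library_tsv(path)

    def test_algebra_commutes_with_roundtrip(self, tmp_path):
        """hybrid merge then round-trip == round-trip then hybrid merge."""
        exp = toy_library(["@AAADETSK"], source="direct_DIA")
        pred = toy_library(["@AAADETSK", "@CCCDETSK"])
        merged = lo.merge_hybrid(exp, pred)
        p1, p2, p3 = (tmp_path / f"{i}.tsv" for i in range(3))
        lo.write_library_tsv(merged, p1)
        lo.write_library_tsv(exp, p2)
        lo.write_library_tsv(pred, p3)
        direct = lo.read_library_tsv(p1)
        indirect = lo.merge_hybrid(lo.read_library_tsv(p2), lo.read_library_tsv(p3))
        assert set(direct.keys()) == set(indirect.keys())
        for k in direct.keys():
            assert direct.get(k).source == indirect.get(k).source


class TestIdTable:
    def make_table(self, tmp_path, fraction_below):
        cfg = sd.GeneratorConfig(seed=21, n_peptides=40, min_len=7, max_len=12)
        prs = sd.gen_peptides(cfg)
        spectra = sd.gen_ground_truth_spectra(prs, cfg)
        rts = sd.gen_ground_truth_rt([p.peptide for p in prs], cfg)
        df = sd.gen_identification_tables(prs, spectra, rts, cfg, fraction_below)
        path = tmp_path / "ids.tsv"
        df.to_csv(path, sep="\t", index=False)
        return path, df

    def test_localization_threshold_strictly_above(self, tmp_path):
        path, df = self.make_table(tmp_path, fraction_below=0.25)
        entries = lo.read_id_table(path)
        kept = (df["LocalizationProb"] > 0.75).sum()
        assert len(entries) == kept
        assert all(e.localization_prob > 0.75 for e in entries)

    def test_boundary_value_excluded(self, tmp_path):
        path, df = self.make_table(tmp_path, fraction_below=0.0)
        df.loc[0, "LocalizationProb"] = 0.75
        df.to_csv(path, sep="\t", index=False)
        entries = lo.read_id_table(path)
        assert len(entries) == len(df) - 1

    def test_all_kept_when_no_low_rows(self, tmp_path):
        path, df = self.make_table(tmp_path, fraction_below=0.0)
        assert len(lo.read_id_table(path)) == len(df)

    def test_bad_fragment_annotation_dropped_entry_kept(self, tmp_path):
        path, df = self.make_table(tmp_path, fraction_below=0.0)
        df.loc[0, "Peaks"] = df.loc[0, "Peaks"] + ";z9+5-weird:0.5"
        df.to_csv(path, sep="\t", index=False)
        entries = lo.read_id_table(path)
        assert len(entries) == len(df)

    def test_unknown_dialect(self, tmp_path):
        path, _ = self.make_table(tmp_path, fraction_below=0.0)
        with pytest.raises(ValueError):
            lo.read_id_table(path, dialect="skyline")

    def test_roundtrip_spectra_preserved(self, tmp_path):
        cfg = sd.GeneratorConfig(seed=22, n_peptides=10, min_len=7, max_len=10)
        prs = sd.gen_peptides(cfg)
        spectra = sd.gen_ground_truth_spectra(prs, cfg)
        rts = sd.gen_ground_truth_rt([p.peptide for p in prs], cfg)
        df = sd.gen_identification_tables(prs, spectra, rts, cfg, 0.0)
        path = tmp_path / "ids.tsv"
        df.to_csv(path, sep="\t", index=False)
        entries = {e.key: e for e in lo.read_id_table(path)}
        for r, pr in enumerate(prs):
            e = entries[pr.key]
            L = spectra.shape[1]
            mat = lo.matrix_from_peaks(pr.peptide, list(e.peaks), L)
            valid = spectra[r] != -1.0
            np.testing.assert_allclose(mat[valid], spectra[r][valid], atol=1e-5)
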