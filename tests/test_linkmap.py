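"""Variant filtering, two-point linkage, clustering, ordering, map assembly."""

import numpy as np
import pandas as pd
import pytest

from radsexlink import (
    FilterParams,
    GenotypeTable,
    build_maps,
    call_sex_linked_from_known_sex,
    classify_informativeness,
    cluster_lod,
    estimate_rf,
    filter_variants,
    haldane,
    inverse_haldane,
    join_singles,
    order_markers,
)
from radsexlink.linkmap import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    PATERNAL,
    MATERNAL,
    SEX_AVERAGED,
    _variant_pairwise,
    pairwise_two_point,
    shrink_rf,
    transmissions,
)

from conftest import SIM_JOIN_LOD, SIM_LOD_LIMIT, SIM_MIN_GROUP, true_chromosome_labels


# ---------------------------------------------------------------------------
# helpers


def table_from_transmissions(t_by_marker: dict[str, list[int]]) -> GenotypeTable:
    """Family table with paternal-only markers realising given transmissions.

    Father 0/1, mother 0/0: an offspring's code equals the transmitted
    paternal allele (0 -> 0/0, 1 -> 0/1), so two-point counts are exact.
    """
    n_off = len(next(iter(t_by_marker.values())))
    samples = ["father", "mother"] + [f"o{i}" for i in range(n_off)]
    rows = {m: [HET, HOM_REF] + list(t) for m, t in t_by_marker.items()}
    calls = pd.DataFrame.from_dict(rows, orient="index", columns=samples).astype(np.int8)
    meta = pd.DataFrame(
        {"locus": list(t_by_marker), "pseudo": False}, index=calls.index
    )
    return classify_informativeness(GenotypeTable(calls, "father", "mother", meta))


HALDANE_CASES = [(0.0, 0.0), (0.2, 25.541281188299534), (0.49, 195.60115027140994)]


# ---------------------------------------------------------------------------


class TestHaldane:
    @pytest.mark.parametrize("r,d", HALDANE_CASES)
    def test_closed_form_values(self, r, d):
        assert haldane(r) == pytest.approx(d, abs=1e-9)

    def test_round_trip_to_1e12(self):
        r = np.linspace(0.0, 0.49, 1001)
        assert np.max(np.abs(inverse_haldane(haldane(r)) - r)) < 1e-12


class TestFilterVariants:
    @pytest.fixture()
    def vcf_path(self, tmp_path):
        samples = ["father", "mother"] + [f"o{i}" for i in range(18)]

        def row(chrom, pos, ref, alt, info, gts, dp=30):
            cells = "\t".join(f"{g}:{dp}" for g in gts)
            return f"{chrom}\t{pos}\t{chrom}:{pos}\t{ref}\t{alt}\t.\tPASS\t{info}\tGT:DP\t{cells}\n"

        het9 = ["0/1", "0/0"] + ["0/1"] * 9 + ["0/0"] * 9  # freq 10/40 = 0.25
        lines = [
            "##fileformat=VCFv4.2\n",
            '##INFO=<ID=PSEUDO,Number=0,Type=Flag,Description="x">\n',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">\n',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">\n',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n",
            row("L1", 1, "A", "C", ".", het9),                       # keeps (thinning rep)
            row("L1", 2, "A", "C", ".", het9),                       # thinned away
            row("L1", 3, "A", "C", ".", het9),                       # thinned away
            row("L2", 1, "AT", "A", ".", het9),                      # indel -> removed
            row("L3", 1, "A", "C", ".", ["./."] * 2 + het9[2:]),     # 10% missing -> removed
            row("L4", 1, "A", "C", ".", het9, dp=5),                 # mean depth 5 -> removed
            row("L5", 1, "A", "C", ".", ["0/1", "0/0"] + ["0/0"] * 16 + ["0/1", "0/1"]),  # maf 0.1 -> removed
            row("L6", 1, "A", "T", "PSEUDO=1", ["0/1", "0/0"] + ["0/0"] * 18, dp=0),      # pseudo bypasses maf/depth
            row("L7", 1, "A", "C", ".", ["./."] + het9[1:]),         # exactly 5% missing -> kept
        ]
        p = tmp_path / "family.vcf"
        p.write_text("".join(lines))
        return p

    def test_filters_apply_with_strict_inequalities(self, vcf_path):
        table = filter_variants(vcf_path)
        loci = set(table.meta["locus"])
        assert loci == {"L1", "L6", "L7"}
        assert len(table.meta[table.meta["locus"] == "L1"]) == 1  # one SNP per locus
        assert bool(table.meta.loc[table.meta["locus"] == "L6", "pseudo"].iloc[0])

    def test_pre_thinning_snps_retained_for_counting(self, vcf_path):
        table = filter_variants(vcf_path)
        assert len(table.snp_table[table.snp_table["locus"] == "L1"]) == 3

    def test_missing_parent_column_rejected(self, vcf_path):
        with pytest.raises(ValueError):
            filter_variants(vcf_path, father="nonexistent")


class TestClassification:
    @pytest.mark.parametrize(
        "fa,mo,expected",
        [
            (HET, HOM_REF, "paternal-only"),
            (HET, HOM_ALT, "paternal-only"),
            (HOM_REF, HET, "maternal-only"),
            (HET, HET, "both"),
            (HOM_REF, HOM_REF, "uninformative"),
            (MISSING, HET, "uninformative"),
        ],
    )
    def test_classes_follow_parental_heterozygosity(self, fa, mo, expected):
        calls = pd.DataFrame(
            {"father": [fa], "mother": [mo], "o1": [0], "o2": [0]},
            index=["m"], dtype=np.int8,
        )
        meta = pd.DataFrame({"locus": ["m"], "pseudo": [False]}, index=["m"])
        t = classify_informativeness(GenotypeTable(calls, "father", "mother", meta))
        assert t.meta.loc["m", "informativeness"] == expected


class TestTwoPoint:
    def test_zero_recombinants_hits_lod_closed_form(self):
        t = table_from_transmissions({"a": [0, 1] * 10, "b": [0, 1] * 10})
        res = estimate_rf(t, "a", "b", PATERNAL)
        assert res.n == 20 and res.k == 0 and res.rf == 0.0
        assert res.lod == pytest.approx(20 * np.log10(2), abs=1e-9)  # 6.0206

    def test_free_recombination_gives_zero_lod(self):
        t = table_from_transmissions({"a": [0] * 10 + [1] * 10, "b": ([0, 1] * 10)})
        res = estimate_rf(t, "a", "b", PATERNAL)
        assert res.n == 20 and res.k == 10
        assert res.rf == 0.5 and res.lod == pytest.approx(0.0, abs=1e-12)

    def test_phase_flip_minimises_recombinants(self):
        base = [0, 1] * 10
        flipped = [1 - v for v in base]
        flipped[0], flipped[5] = base[0], base[5]  # 18 raw recombinants
        t = table_from_transmissions({"a": base, "b": flipped})
        res = estimate_rf(t, "a", "b", PATERNAL)
        assert res.k == 2 and res.rf == pytest.approx(0.1)

    def test_min_error_shrinkage(self):
        assert shrink_rf(0.02, 0.02) == 0.0
        assert shrink_rf(0.0, 0.02) == 0.0
        assert shrink_rf(0.2, 0.02) == pytest.approx((0.2 - 0.02) / 0.96)

    def test_lod_invariant_to_pair_order_and_allele_relabelling(self):
        rng = np.random.default_rng(0)
        ta = list(rng.integers(0, 2, 30))
        tb = list(rng.integers(0, 2, 30))
        t = table_from_transmissions({"a": ta, "b": tb})
        ab = estimate_rf(t, "a", "b", PATERNAL)
        ba = estimate_rf(t, "b", "a", PATERNAL)
        assert ab.lod == pytest.approx(ba.lod) and ab.rf == pytest.approx(ba.rf)
        # relabel marker b's alleles globally (swap hom-ref <-> hom-alt,
        # mother becomes 1/1): transmissions complement, LOD unchanged
        relabeled = table_from_transmissions({"a": ta, "b": [1 - v for v in tb]})
        rel = estimate_rf(relabeled, "a", "b", PATERNAL)
        assert rel.lod == pytest.approx(ab.lod)

    def test_both_informative_pairs_use_unambiguous_offspring_only(self):
        # both parents het; offspring het at a marker is not scorable there
        samples = ["father", "mother", "o1", "o2", "o3", "o4"]
        calls = pd.DataFrame(
            {
                "father": [HET, HET],
                "mother": [HET, HET],
                "o1": [HOM_REF, HOM_REF],
                "o2": [HOM_ALT, HOM_ALT],
                "o3": [HET, HOM_REF],
                "o4": [HOM_REF, HET],
            },
            index=["a", "b"], dtype=np.int8,
        )[samples]
        meta = pd.DataFrame({"locus": ["a", "b"], "pseudo": False}, index=["a", "b"])
        t = classify_informativeness(GenotypeTable(calls, "father", "mother", meta))
        res = estimate_rf(t, "a", "b", PATERNAL)
        assert res.n == 2  # only o1 and o2 scorable at both markers

    def test_undefined_pair_is_flagged(self):
        # marker b maternal-only: no paternal transmissions
        calls = pd.DataFrame(
            {
                "father": [HET, HOM_REF],
                "mother": [HOM_REF, HET],
                "o1": [HOM_REF, HOM_REF],
            },
            index=["a", "b"], dtype=np.int8,
        )
        meta = pd.DataFrame({"locus": ["a", "b"], "pseudo": False}, index=["a", "b"])
        t = classify_informativeness(GenotypeTable(calls, "father", "mother", meta))
        res = estimate_rf(t, "a", "b", PATERNAL)
        assert res.n == 0 and np.isnan(res.lod)


class TestClustering:
    def _lod_from(self, t_by_marker):
        t = table_from_transmissions(t_by_marker)
        _, _, _, lod = pairwise_two_point(transmissions(t, PATERNAL))
        return lod

    def test_threshold_above_all_lods_gives_singletons(self):
        rng = np.random.default_rng(1)
        lod = self._lod_from({f"m{i}": list(rng.integers(0, 2, 20)) for i in range(6)})
        groups, singles = cluster_lod(lod, lod_limit=1e6)
        assert groups == [] and len(singles) == 6

    def test_grouping_invariant_to_marker_order(self):
        rng = np.random.default_rng(2)
        t = {f"m{i}": list(rng.integers(0, 2, 40)) for i in range(10)}
        lod = self._lod_from(t)
        g1, s1 = cluster_lod(lod, 3.0)
        perm = list(rng.permutation(lod.index))
        g2, s2 = cluster_lod(lod.loc[perm, perm], 3.0)
        assert g1 == g2 and s1 == s2

    def test_three_chromosome_family_recovered_exactly(self, tmp_path):
        from sklearn.metrics import adjusted_rand_score

        # 3 chromosomes, 300 loci, as a dedicated small genome
        from radsexlink import build_genome, place_loci, simulate_family, SimParams
        from radsexlink import io as rio
        from radsexlink import encode_presence_absence, merge_calls

        genome = build_genome(
            {"n_chromosomes": 3, "female_total_cM": 420, "male_total_cM": 330,
             "sex_chromosome_index": 1, "seed": 21}
        )
        params = SimParams(seed=21, n_loci=300, n_y_loci=10)
        catalog, truth = place_loci(genome, params)
        fam = simulate_family(genome, catalog, truth, params)
        vcf = tmp_path / "fam3.vcf"
        rio.write_family_vcf(fam.genotypes, vcf)
        table = filter_variants(vcf)
        merged = classify_informativeness(
            merge_calls(table, encode_presence_absence(fam.y_depth, truth.y_loci))
        )
        _, _, lod = _variant_pairwise(merged, SEX_AVERAGED, 0.02)
        groups, singles = cluster_lod(lod, SIM_LOD_LIMIT)
        groups, _ = join_singles(lod, groups, singles, SIM_JOIN_LOD)
        groups = [g for g in groups if len(g) >= SIM_MIN_GROUP]
        assert len(groups) == 3
        lab_t, lab_p = [], []
        for gi, g in enumerate(groups):
            for m in g:
                lab_t.append(truth.table.loc[merged.meta.loc[m, "locus"], "chrom"])
                lab_p.append(gi)
        assert adjusted_rand_score(lab_t, lab_p) == 1.0


class TestJoinSingles:
    def _setup(self):
        markers = ["a", "b", "c", "d", "s"]
        lod = pd.DataFrame(0.0, index=markers, columns=markers)
        lod.loc["a", "b"] = lod.loc["b", "a"] = 30.0
        lod.loc["c", "d"] = lod.loc["d", "c"] = 30.0
        return lod

    def test_single_below_limit_stays_unplaced(self):
        lod = self._setup()
        lod.loc["s", "a"] = lod.loc["a", "s"] = 14.9
        groups, rem = join_singles(lod, [["a", "b"], ["c", "d"]], ["s"], 15.0)
        assert rem == ["s"] and all("s" not in g for g in groups)

    def test_single_joins_its_best_group(self):
        lod = self._setup()
        lod.loc["s", "c"] = lod.loc["c", "s"] = 16.0
        groups, rem = join_singles(lod, [["a", "b"], ["c", "d"]], ["s"], 15.0)
        assert rem == [] and "s" in groups[1]

    def test_withheld_markers_rejoin_their_true_group(self, default_run):
        rng = np.random.default_rng(0)
        table = default_run["table"]
        _, _, lod = _variant_pairwise(table, SEX_AVERAGED, 0.02)
        groups, singles = cluster_lod(lod, SIM_LOD_LIMIT)
        groups = [g for g in groups if len(g) >= SIM_MIN_GROUP]
        membership = {m: gi for gi, g in enumerate(groups) for m in g}
        withheld = list(rng.choice(sorted(membership), size=60, replace=False))
        pruned = [[m for m in g if m not in withheld] for g in groups]
        joined, rem = join_singles(lod, pruned, withheld, SIM_JOIN_LOD)
        back = {m: gi for gi, g in enumerate(joined) for m in g}
        correct = sum(back.get(m) == membership[m] for m in withheld)
        assert correct / len(withheld) >= 0.95


class TestOrdering:
    def test_two_marker_group_length_is_haldane_distance(self):
        rf = pd.DataFrame([[0.0, 0.2], [0.2, 0.0]], index=["a", "b"], columns=["a", "b"])
        ids, pos = order_markers(["a", "b"], rf)
        assert pos[-1] == pytest.approx(-50 * np.log(0.6), abs=1e-9)  # 25.54

    def test_cosegregating_chain_collapses_to_zero(self):
        m = [f"m{i}" for i in range(5)]
        rf = pd.DataFrame(0.0, index=m, columns=m)
        ids, pos = order_markers(m, rf)
        assert np.allclose(pos, 0.0)

    def test_single_marker_group_unchanged(self):
        rf = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        ids, pos = order_markers(["a"], rf)
        assert ids == ["a"] and pos[0] == 0.0

    def test_shuffled_chain_recovered_in_at_least_18_of_20_seeds(self):
        from radsexlink.linkmap import pairwise_two_point

        recovered = 0
        shuffler = np.random.default_rng(99)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_m, n_off = 12, 146
            t = np.zeros((n_m, n_off))
            t[0] = rng.random(n_off) < 0.5
            for i in range(1, n_m):  # true neighbour rf 0.05
                flip = rng.random(n_off) < 0.05
                t[i] = np.where(flip, 1 - t[i - 1], t[i - 1])
            frame = pd.DataFrame(t, index=[f"m{i:02d}" for i in range(n_m)])
            _, _, rf, _ = pairwise_two_point(frame)
            rf_adj = pd.DataFrame(
                shrink_rf(rf.to_numpy(), 0.02), index=rf.index, columns=rf.columns
            )
            ids, _ = order_markers(list(shuffler.permutation(frame.index)), rf_adj)
            truth = [f"m{i:02d}" for i in range(n_m)]
            recovered += ids == truth or ids == truth[::-1]
        assert recovered >= 18


class TestBuildMaps:
    def test_pseudo_markers_absent_from_maternal_map(self, default_run):
        maps = default_run["maps"]
        assert not maps[MATERNAL].table["pseudo"].any()
        assert maps[PATERNAL].table["pseudo"].sum() > 0
        assert maps[SEX_AVERAGED].table["pseudo"].sum() > 0

    def test_group_numbering_shared_across_variants(self, default_run):
        maps = default_run["maps"]
        shared = maps[PATERNAL].table.index.intersection(maps[MATERNAL].table.index)
        assert len(shared) > 0
        assert (
            maps[PATERNAL].table.loc[shared, "group"]
            == maps[MATERNAL].table.loc[shared, "group"]
        ).all()

    def test_all_both_informative_input_gives_equal_marker_sets(self):
        rng = np.random.default_rng(3)
        n_off = 80
        samples = ["father", "mother"] + [f"o{i}" for i in range(n_off)]
        rows = {}
        for i in range(12):  # tightly linked both-informative chain
            if i == 0:
                pat = rng.integers(0, 2, n_off)
                mat = rng.integers(0, 2, n_off)
            geno = pat + mat
            rows[f"m{i:02d}"] = [HET, HET] + list(geno)
        calls = pd.DataFrame.from_dict(rows, orient="index", columns=samples).astype(np.int8)
        meta = pd.DataFrame({"locus": list(rows), "pseudo": False}, index=calls.index)
        t = classify_informativeness(GenotypeTable(calls, "father", "mother", meta))
        maps = build_maps(t, lod_limit=3, join_lod=3)
        assert set(maps[PATERNAL].table.index) == set(maps[MATERNAL].table.index)

    def test_positions_non_decreasing_within_groups(self, default_run):
        for lmap in default_run["maps"].values():
            for g in lmap.groups:
                pos = lmap.group_markers(g)["position_cM"].to_numpy()
                assert (np.diff(pos) >= -1e-12).all()

    def test_y_pseudo_cluster_on_single_paternal_group(self, pipeline_runs):
        for run in pipeline_runs.values():
            pat = run["maps"][PATERNAL].table
            pseudo = pat[pat["pseudo"]]
            assert pseudo["group"].nunique() == 1


class TestKnownSexCalling:
    def test_perfect_concordance_flagged(self):
        t = table_from_transmissions({"y": [1] * 73 + [0] * 73, "a": [0, 1] * 73})
        sexes = pd.Series(
            ["male"] * 73 + ["female"] * 73, index=[f"o{i}" for i in range(146)]
        )
        res = call_sex_linked_from_known_sex(t, sexes)
        assert bool(res.loc["y", "flagged"])
        assert not bool(res.loc["a", "flagged"])

    def test_autosomal_markers_rarely_flagged_on_simulation(self, clean_run):
        table = clean_run["table"]
        fam = clean_run["family"]
        res = call_sex_linked_from_known_sex(table, fam.offspring_sex)
        meta = table.meta
        truth = clean_run["truth"].table
        autosomal = [
            m for m in res.index
            if not meta.loc[m, "pseudo"]
            and truth.loc[meta.loc[m, "locus"], "chrom"] != clean_run["genome"].sex_chromosome
        ]
        assert res.loc[autosomal, "flagged"].mean() <= 0.01
        # every pseudo-marker is perfectly sex-concordant in the clean family
        pseudo = [m for m in res.index if meta.loc[m, "pseudo"]]
        assert res.loc[pseudo, "flagged"].all()

    def test_missing_offspring_sexes_rejected(self, clean_run):
        with pytest.raises(ValueError):
            call_sex_linked_from_known_sex(clean_run["table"], pd.Series(dtype=object))
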