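"""Tests for the simulators and the packaged printed-table fixtures."""

import numpy as np
import pytest

from mirflux.errors import ConfigurationError, TableParseError
from mirflux.quant import AdapterSpec, Read, quantify_reads
from mirflux.synthetic import (
    PlantedUTRs,
    SimulationConfig,
    load_printed_table,
    make_mirna_reference,
    packaged_table,
    plant_mre_sites,
    simulate_count_matrix,
    simulate_small_rna_reads,
)


# ---------------------------------------------------------------------------
# config validation
# ---------------------------------------------------------------------------

class TestSimulationConfig:
    def test_offset_probs_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(seed=1, read_5p_offset_probs={0: 0.5})

    def test_replicates_minimum(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(seed=1, n_samples_per_group=1)

    def test_dispersion_positive(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(seed=1, nb_dispersion=0.0)

    def test_seed_must_be_integer(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(seed="7")


# ---------------------------------------------------------------------------
# reference generator
# ---------------------------------------------------------------------------

class TestMakeReference:
    def test_minimal_single_mirna(self):
        ref = make_mirna_reference(SimulationConfig(seed=1, n_mirnas=1))
        assert len(ref.annotations) == 1
        assert len(ref.annotations[0].loci) == 1

    def test_determinism_byte_identical(self):
        a = make_mirna_reference(SimulationConfig(seed=1, n_mirnas=20))
        b = make_mirna_reference(SimulationConfig(seed=1, n_mirnas=20))
        assert a.genome_fasta() == b.genome_fasta()
        assert a.mature_fasta() == b.mature_fasta()
        assert a.annotation_gff3() == b.annotation_gff3()

    def test_different_seeds_differ(self):
        a = make_mirna_reference(SimulationConfig(seed=1, n_mirnas=20))
        b = make_mirna_reference(SimulationConfig(seed=2, n_mirnas=20))
        assert {x.sequence for x in a.annotations} != {x.sequence for x in b.annotations}

    def test_postconditions(self, reference):
        for ann in reference.annotations:
            assert 19 <= len(ann.sequence) <= 23
        assert any(len(a.loci) >= 2 for a in reference.annotations)
        seqs = {}
        shared = False
        for a in reference.annotations:
            for b_name, b_seq in seqs.items():
                longest = _longest_common_substring(a.sequence, b_seq)
                if longest >= 16:
                    shared = True
            seqs[a.name] = a.sequence
        assert shared, "no pair of distinct miRNAs shares a >=16 nt stretch"

    def test_matures_embedded_at_annotated_loci(self, reference):
        for ann in reference.annotations:
            for loc in ann.loci:
                contig = reference.genome[loc.seqid]
                start = loc.five_prime_start - 1
                assert contig[start:start + len(ann.sequence)] == ann.sequence


def _longest_common_substring(a, b):
    best = 0
    for i in range(len(a)):
        for j in range(i + best + 1, len(a) + 1):
            if a[i:j] in b:
                best = j - i
            else:
                break
    return best


# ---------------------------------------------------------------------------
# read simulator
# ---------------------------------------------------------------------------

class TestSimulateReads:
    def test_all_offsets_zero(self, reference):
        cfg = SimulationConfig(seed=5, read_5p_offset_probs={0: 1.0})
        sim = simulate_small_rna_reads(cfg, reference, n_reads=200)
        assert (sim.truth["offset"] == 0).all()

    def test_truth_table_complete(self, reference, config):
        sim = simulate_small_rna_reads(config, reference, n_reads=300,
                                       decoy_fraction=0.3)
        assert len(sim.truth) == 300
        assert set(sim.truth["read_id"]) == {rid for rid, _ in sim.reads}
        nondecoy = sim.truth[sim.truth["source"] != "decoy"]
        assert nondecoy["offset"].notna().all()

    def test_determinism(self, reference):
        cfg = SimulationConfig(seed=9)
        a = simulate_small_rna_reads(cfg, reference, n_reads=100, decoy_fraction=0.1)
        b = simulate_small_rna_reads(cfg, reference, n_reads=100, decoy_fraction=0.1)
        assert a.fastq() == b.fastq()
        assert a.truth.equals(b.truth)

    def test_decoy_fraction_binomial(self, reference):
        cfg = SimulationConfig(seed=7)
        sim = simulate_small_rna_reads(cfg, reference, n_reads=10_000,
                                       decoy_fraction=0.2)
        n_decoys = (sim.truth["source"] == "decoy").sum()
        # 4 sigma around np = 2000, sigma = sqrt(n p (1-p)) = 40
        assert abs(n_decoys - 2000) < 160

    def test_short_adapter_rejected(self, reference):
        cfg = SimulationConfig(seed=1, adapter="ACGTAC")
        with pytest.raises(ConfigurationError):
            simulate_small_rna_reads(cfg, reference)

    def test_full_assignment_when_offsets_in_window(self, config, reference):
        """After the full pipeline, every non-decoy read is assigned."""
        sim = simulate_small_rna_reads(config, reference, n_reads=1000)
        reads = [Read(rid, seq) for rid, seq in sim.reads]
        res = quantify_reads(reads, reference.genome, reference.annotations,
                             adapter=AdapterSpec(config.adapter), window=5)
        assert res.n_assigned_reads == 1000
        assert sum(res.counts.values()) == 1000


# ---------------------------------------------------------------------------
# count-matrix simulator
# ---------------------------------------------------------------------------

class TestSimulateCounts:
    def test_null_group_means_close(self):
        cfg = SimulationConfig(seed=3, n_genes=300, n_samples_per_group=50,
                               groups=("TA", "NAWD"), k_unwanted=0,
                               nb_dispersion=0.05)
        sim = simulate_count_matrix(cfg)
        ta = [s for s, g in sim.design.items() if g == "TA"]
        wd = [s for s, g in sim.design.items() if g == "NAWD"]
        ratio = sim.table.counts[wd].mean(axis=1) / sim.table.counts[ta].mean(axis=1)
        assert np.median(ratio) == pytest.approx(1.0, abs=0.1)

    def test_planted_fc_mean_ratio(self):
        # 200 features with planted FC 4 act as Monte-Carlo replicates
        feats = {f"gene{i:05d}": 4.0 for i in range(200)}
        cfg = SimulationConfig(seed=4, n_genes=200, n_samples_per_group=5,
                               groups=("TA", "NAWD"), k_unwanted=0,
                               nb_dispersion=0.05, effect_fold_changes=feats)
        sim = simulate_count_matrix(cfg)
        ta = [s for s, g in sim.design.items() if g == "TA"]
        wd = [s for s, g in sim.design.items() if g == "NAWD"]
        sf = sim.truth["size_factors"]
        norm = sim.table.counts.div(sf, axis=1)
        ratios = norm[wd].mean(axis=1) / norm[ta].mean(axis=1)
        assert 3.0 <= ratios.mean() <= 5.3

    def test_nb_moments(self):
        alpha = 0.2
        cfg = SimulationConfig(seed=8, n_genes=60, n_samples_per_group=400,
                               groups=("TA", "NAWD"), k_unwanted=0,
                               nb_dispersion=alpha)
        sim = simulate_count_matrix(cfg)
        counts = sim.table.counts.to_numpy(dtype=float)
        sf = sim.truth["size_factors"].to_numpy()
        norm = counts / sf[None, :]
        m = norm.mean(axis=1)
        v = norm.var(axis=1, ddof=1)
        expected = m * (1 + alpha * m)
        assert np.median(v / expected) == pytest.approx(1.0, abs=0.15)

    def test_svd_recovers_planted_factor(self):
        cfg = SimulationConfig(seed=6, n_genes=800, n_samples_per_group=5,
                               groups=("TA", "NAWD"), k_unwanted=1,
                               factor_loadings_scale=1.0, nb_dispersion=0.05)
        sim = simulate_count_matrix(cfg)
        logc = np.log(sim.table.counts.to_numpy(dtype=float).T + 0.5)
        logc -= logc.mean(axis=0, keepdims=True)
        u, _, _ = np.linalg.svd(logc, full_matrices=False)
        truth = sim.truth["factor_scores"]["W1"].to_numpy()
        assert abs(np.corrcoef(u[:, 0], truth)[0, 1]) > 0.9

    def test_determinism(self):
        cfg = SimulationConfig(seed=12, n_genes=50)
        a = simulate_count_matrix(cfg)
        b = simulate_count_matrix(cfg)
        assert a.table.counts.equals(b.table.counts)

    def test_unknown_effect_feature_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_count_matrix(SimulationConfig(
                seed=1, n_genes=10, effect_fold_changes={"nope": 2.0}))


# ---------------------------------------------------------------------------
# planted MRE sites
# ---------------------------------------------------------------------------

MIRNAS = {"mirA": "UACCUCAGUUGGCAAUACCU", "mirB": "ACGGUUCAAGGCUAACCGGA"}


class TestPlantSites:
    def test_single_8mer_round_trip(self):
        from mirflux.targetnet import MiRNASeq, seed_match_scan
        planted = plant_mre_sites({"utr1": 400},
                                  [("mirA", "utr1", "8mer", 100)],
                                  MIRNAS, seed=2)
        sites = seed_match_scan(MiRNASeq("mirA", MIRNAS["mirA"]), "utr1",
                                planted.utrs["utr1"])
        assert [(s.site_type, s.start, s.end) for s in sites] == [("8mer", 100, 107)]

    def test_empty_plan_no_sites(self):
        from mirflux.targetnet import MiRNASeq, seed_match_scan
        planted = plant_mre_sites({"utr1": 300}, [], MIRNAS, seed=3)
        for name, seq in MIRNAS.items():
            assert seed_match_scan(MiRNASeq(name, seq), "utr1",
                                   planted.utrs["utr1"]) == []

    def test_site_flush_with_utr_end(self):
        from mirflux.targetnet import MiRNASeq, seed_match_scan
        length = 250
        planted = plant_mre_sites({"utr1": length},
                                  [("mirA", "utr1", "7mer-m8", length - 6)],
                                  MIRNAS, seed=4)
        sites = seed_match_scan(MiRNASeq("mirA", MIRNAS["mirA"]), "utr1",
                                planted.utrs["utr1"])
        assert [(s.site_type, s.start, s.end) for s in sites] == \
            [("7mer-m8", length - 6, length)]

    def test_overlapping_same_mirna_rejected(self):
        with pytest.raises(ValueError):
            plant_mre_sites({"utr1": 300},
                            [("mirA", "utr1", "8mer", 100),
                             ("mirA", "utr1", "7mer-m8", 104)],
                            MIRNAS, seed=5)

    def test_site_exceeding_utr_rejected(self):
        with pytest.raises(ValueError):
            plant_mre_sites({"utr1": 100}, [("mirA", "utr1", "8mer", 95)],
                            MIRNAS, seed=6)

    def test_truth_list_matches_plan(self):
        plan = [("mirA", "utr1", "8mer", 50), ("mirB", "utr1", "7mer-A1", 200),
                ("mirA", "utr2", "7mer-m8", 10)]
        planted = plant_mre_sites({"utr1": 300, "utr2": 120}, plan, MIRNAS, seed=7)
        assert sorted(planted.truth) == sorted([
            ("mirA", "utr1", "8mer", 50, 57),
            ("mirB", "utr1", "7mer-A1", 200, 206),
            ("mirA", "utr2", "7mer-m8", 10, 16)])


# ---------------------------------------------------------------------------
# printed-table fixtures
# ---------------------------------------------------------------------------

class TestPrintedTables:
    def test_ipn_contains_pfn2_row(self):
        table = packaged_table("IPN")
        match = [r for r in table.rows
                 if r.mrna == "Pfn2" and r.start == 452]
        assert len(match) == 1
        r = match[0]
        assert (r.mrna_fc, r.mrna_fdr) == (0.496, 8.36e-09)
        assert (r.mirna, r.mirna_fc, r.mirna_fdr) == ("miR-106b-5p", 1.789, 9.32e-11)
        assert (r.seed_type, r.start, r.end) == ("7mer-m8", 452, 458)

    def test_mhb_contains_arf5_row(self):
        table = packaged_table("MHb")
        match = [r for r in table.rows if r.mrna == "Arf5"]
        assert len(match) == 1
        r = match[0]
        assert (r.mrna_fc, r.mrna_fdr) == (4.543, 1.01e-24)
        assert (r.mirna, r.mirna_fc, r.mirna_fdr) == ("miR-29b-3p", 0.650, 4.95e-06)
        assert (r.seed_type, r.start, r.end) == ("8mer", 392, 399)

    def test_row_counts(self):
        assert len(packaged_table("IPN").rows) == 82
        assert len(packaged_table("MHb").rows) == 101

    def test_empty_file_is_parse_error(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(TableParseError):
            load_printed_table(p, "IPN")

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("mrna\tmrna_fc\tmrna_fdr\tmirna\tmirna_fc\tmirna_fdr"
                     "\tseed_type\tstart\tend\n"
                     "G\t2.5\t0.001\tmiR-1\t0.5\t0.001\t9mer\t10\t16\n")
        with pytest.raises(TableParseError, match="line 2"):
            load_printed_table(p, "IPN")

    @pytest.mark.parametrize("region", ["IPN", "MHb"])
    def test_fixture_integrity(self, region):
        table = packaged_table(region)
        for r in table.rows:
            assert r.mrna_fdr < 0.01 and r.mirna_fdr < 0.01
            assert r.mrna_fc > 2 or r.mrna_fc < 0.5
            span = r.end - r.start + 1
            assert span == (8 if r.seed_type == "8mer" else 7)
            # reciprocal direction as printed
            assert (r.mrna_fc > 1) != (r.mirna_fc > 1)
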