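import numpy as np
import pandas as pd
import pytest

from cleavecat.simulate import (GroundTruth, SimulationConfig, SizingError,
                                generate_assembler_outputs,
                                generate_conservation, generate_coverage,
                                generate_expression, generate_genome,
                                simulate)
from cleavecat.tracks import transcript_conservation, transcript_integrity
from cleavecat.transcripts import structure_key

from oracles import oracle_integrity


def small_config(**kw):
    base = dict(seed=5, n_chromosomes=2, chrom_length=400_000,
                n_coding_genes=30, n_lncRNA_genes=20)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_probability_out_of_range(self):
        with pytest.raises(ValueError):
            small_config(assembler_dropout=1.5).validate()

    def test_stage_design_must_sum(self):
        with pytest.raises(ValueError):
            small_config(stage_design=(("oocyte", "WT", 4),)).validate()

    def test_counts_positive(self):
        with pytest.raises(ValueError):
            small_config(n_coding_genes=0).validate()

    def test_sizing_error(self):
        with pytest.raises(SizingError):
            generate_genome(small_config(chrom_length=50_000,
                                         n_coding_genes=200))


class TestGenome:
    def test_canonical_splice_motifs_on_strand(self, tiny_sim):
        # construction guarantee, verified by direct genome scanning
        genome = tiny_sim.genome
        for t in tiny_sim.truth_transcripts:
            for a, b in t.introns():
                left = genome[t.chrom][a:a + 2]
                right = genome[t.chrom][b - 2:b]
                if t.strand == "+":
                    assert (left, right) == ("GT", "AG"), t.transcript_id
                else:
                    assert (left, right) == ("CT", "AC"), t.transcript_id

    def test_seed_determinism_byte_identical(self, tmp_path):
        from cleavecat.io import write_fasta, write_gtf
        cfg = small_config()
        out = []
        for run in (1, 2):
            genome, loci = generate_genome(SimulationConfig(**cfg.__dict__))
            fa = tmp_path / f"g{run}.fa"
            write_fasta(genome, fa)
            out.append(fa.read_bytes())
        assert out[0] == out[1]

    def test_divergent_pair_geometry_by_annotation_scan(self):
        cfg = small_config(n_lncRNA_genes=60, n_coding_genes=60,
                           divergent_pair_fraction=0.5,
                           chrom_length=700_000)
        genome, loci = generate_genome(cfg)
        by_id = {l.transcript_id: l for l in loci}
        n_div = 0
        gaps = []
        for l in loci:
            if l.partner_of is None:
                continue
            n_div += 1
            cod = by_id[l.partner_of]
            assert l.strand != cod.strand
            lnc_tss = l.exons[-1][1] if l.strand == "-" else l.exons[0][0]
            cod_tss = cod.exons[-1][1] if cod.strand == "-" else \
                cod.exons[0][0]
            gaps.append(abs(lnc_tss - cod_tss))
        assert n_div == 30  # 0.5 * 60
        # TSS separations mostly 0-400 bases
        assert np.mean(np.array(gaps) <= 400) > 0.6

    def test_coding_genes_have_orfs_lncs_do_not(self, tiny_sim):
        from cleavecat.coding import coding_score, extract_orf_features
        from cleavecat.transcripts import spliced_sequence
        n_checked = 0
        for t in tiny_sim.truth_transcripts[:40]:
            seq = spliced_sequence(t, tiny_sim.genome)
            f = extract_orf_features(seq)
            s = coding_score(f, t.length)
            if t.biotype == "protein_coding":
                assert s >= -0.5, t.transcript_id
            else:
                assert s < -0.5, t.transcript_id
            n_checked += 1
        assert n_checked


class TestAssemblerOutputs:
    def test_degenerate_parameters_emit_exact_truth(self):
        cfg = small_config(assembler_dropout=0.0, fragmentation_rate=0.0,
                           noise_tx_rate=0.0, detection_min_fpkm=0.0)
        genome, loci = generate_genome(cfg)
        expr, meta, _ = generate_expression(cfg)
        sets_a, sets_b, slots, truth = generate_assembler_outputs(
            loci, expr, cfg)
        truth_keys = {structure_key(l.to_transcript("x")) for l in loci}
        for sets in (sets_a, sets_b):
            for sample, ts in sets.items():
                assert len(ts) == len(loci)
                assert {structure_key(t) for t in ts} == truth_keys

    def test_noise_ids_recorded(self, tiny_sim):
        assert tiny_sim.truth.noise_tx_ids
        for tid in tiny_sim.truth.noise_tx_ids:
            assert tid.startswith("noise")

    def test_dropout_detection_rate_binomial(self):
        # empirical per-slot detection frequency matches 1 - dropout
        cfg = small_config(assembler_dropout=0.5, fragmentation_rate=0.0,
                           detection_min_fpkm=0.0, noise_tx_rate=0.0)
        genome, loci = generate_genome(cfg)
        expr, _, _ = generate_expression(cfg)
        sets_a, sets_b, slots, _ = generate_assembler_outputs(
            loci, expr, cfg)
        n_slots = sum(len(s) for s in slots.values())
        total = len(loci) * cfg.n_samples * 2
        p_hat = n_slots / total
        se = np.sqrt(0.5 * 0.5 / total)
        assert abs(p_hat - 0.5) < 4 * se

    def test_higher_dropout_gives_nested_detection(self):
        cfg_lo = small_config(assembler_dropout=0.1)
        cfg_hi = small_config(assembler_dropout=0.6)
        genome, loci = generate_genome(cfg_lo)
        expr, _, _ = generate_expression(cfg_lo)
        _, _, slots_lo, _ = generate_assembler_outputs(loci, expr, cfg_lo)
        _, _, slots_hi, _ = generate_assembler_outputs(loci, expr, cfg_hi)
        for tid in slots_lo:
            if tid.startswith("noise"):
                continue  # noise placement is not rate-coupled
            assert slots_hi[tid] <= slots_lo[tid]

    def test_appears_in_two_samples_binomial_expectation(self):
        # P(a transcript intact in >= 2 samples of assembler A) across many
        # replicate sub-streams matches the binomial expectation
        cfg = small_config(assembler_dropout=0.5, fragmentation_rate=0.0,
                           detection_min_fpkm=0.0, noise_tx_rate=0.0,
                           n_coding_genes=20, n_lncRNA_genes=10)
        genome, loci = generate_genome(cfg)
        expr, _, _ = generate_expression(cfg)
        hits = trials = 0
        from scipy import stats
        for rep in range(40):
            rng = np.random.default_rng(10_000 + rep)
            _, _, slots, _ = generate_assembler_outputs(
                loci, expr, cfg, rng)
            for tid, sl in slots.items():
                if tid.startswith("noise"):
                    continue
                trials += 1
                if len({s for a, s in sl if a == "A"}) >= 2:
                    hits += 1
        n, p = cfg.n_samples, 0.5
        expect = 1 - stats.binom.cdf(1, n, p)
        se = np.sqrt(expect * (1 - expect) / trials)
        assert abs(hits / trials - expect) < 5 * max(se, 1e-4)


class TestCoverage:
    def test_zero_fpkm_means_zero_coverage(self, tiny_sim):
        expr = tiny_sim.expression
        zero_rows = expr.index[(expr == 0).all(axis=1)]
        by_id = tiny_sim.transcripts_by_id
        for tid in zero_rows:
            t = by_id[tid]
            for cov in tiny_sim.coverage.values():
                assert cov.max_value(t) == 0.0

    def test_gapped_excluded_from_well_reconstructed(self, tiny_sim):
        assert not (tiny_sim.truth.gapped_ids
                    & tiny_sim.truth.well_reconstructed_ids)

    def test_integrity_labels_match_brute_force(self, tiny_sim):
        # brute-force per-base recomputation over the emitted tracks
        by_id = tiny_sim.transcripts_by_id
        checked = 0
        for tid, t in list(by_id.items())[:25]:
            best = max(transcript_integrity(t, cov)
                       for cov in tiny_sim.coverage.values())
            planted_well = tid in tiny_sim.truth.well_reconstructed_ids
            assert (best >= 0.75) == planted_well, tid
            checked += 1
        assert checked

    def test_brute_force_base_count_one_transcript(self, tiny_sim):
        t = next(t for t in tiny_sim.truth_transcripts
                 if t.transcript_id in
                 tiny_sim.truth.well_reconstructed_ids)
        sample = max(tiny_sim.coverage,
                     key=lambda s: tiny_sim.coverage[s].max_value(t))
        cov = tiny_sim.coverage[sample]

        def depth_of(chrom, pos):
            w, v = cov._clip(chrom, pos, pos + 1)
            return float(v[0]) if len(v) else 0.0

        assert transcript_integrity(t, cov) == pytest.approx(
            oracle_integrity(t, depth_of))


class TestExpression:
    def test_fpkm_nonnegative_and_shape(self, tiny_sim):
        expr = tiny_sim.expression
        assert (expr.to_numpy() >= 0).all()
        assert expr.shape[1] == 24

    def test_metadata_design(self, tiny_sim):
        meta = tiny_sim.metadata
        assert list(meta["stage"]).count("2cell") == 8
        assert list(meta["genotype"]).count("dicerKO") == 2
        assert meta["time_index"].max() == 3

    def test_planted_module_eigengene_stage_correlation(self):
        # recompute eigengene from the emitted matrix: "2cell-high" module
        cfg = SimulationConfig(seed=9, n_coding_genes=300,
                               n_lncRNA_genes=200, n_chromosomes=2,
                               chrom_length=2_000_000)
        expr, meta, truth = generate_expression(cfg)
        from cleavecat.network import module_eigengene
        labels = pd.Series(truth.module_labels).reindex(expr.index).fillna(0)
        logx = np.log2(expr + 0.05)
        # module 3 is planted on the (2cell, WT) group
        mes = module_eigengene(logx[labels == 3].pipe(
            lambda df: df), pd.Series(3, index=logx[labels == 3].index))
        e = mes.iloc[0].to_numpy()
        ind = (meta["stage"] == "2cell").to_numpy(dtype=float)
        r = abs(np.corrcoef(e, ind)[0, 1])
        assert r > 0.7

    def test_within_module_correlation_near_target(self):
        cfg = SimulationConfig(seed=9)
        expr, meta, truth = generate_expression(cfg)
        labels = pd.Series(truth.module_labels)
        genes = [g for g, m in labels.items()
                 if m == 1 and g.startswith("cod")][:40]
        logx = np.log2(expr.loc[genes] + 0.05).to_numpy()
        r = np.corrcoef(logx)
        mean_r = r[np.triu_indices(len(genes), 1)].mean()
        assert abs(mean_r - cfg.module_cor) < 0.15

    def test_lnc_max_fpkm_below_mrna(self, fixture_sim):
        expr = fixture_sim.expression
        lnc = [i for i in expr.index if i.startswith("lnc")]
        cod = [i for i in expr.index if i.startswith("cod")]
        assert expr.loc[lnc].max(axis=1).mean() < \
            expr.loc[cod].max(axis=1).mean()


class TestConservation:
    def test_phastcons_in_unit_interval(self, tiny_sim):
        for chrom in tiny_sim.phastcons.chromosomes():
            vals = [v for _, _, v in tiny_sim.phastcons.intervals(chrom)]
            assert min(vals) >= 0 and max(vals) <= 1

    def test_group_means_in_planted_direction(self, tiny_sim):
        # brute-force per-base averaging via the track reader
        cod_means, lnc_means = [], []
        for t in tiny_sim.truth_transcripts:
            m = transcript_conservation(t, tiny_sim.phastcons)
            if m is None:
                continue
            (cod_means if t.biotype == "protein_coding"
             else lnc_means).append(m)
        assert np.mean(cod_means) > np.mean(lnc_means)
        # same direction for the phyloP-like track
        pp_cod = [transcript_conservation(t, tiny_sim.phylop)
                  for t in tiny_sim.truth_transcripts
                  if t.biotype == "protein_coding"]
        pp_lnc = [transcript_conservation(t, tiny_sim.phylop)
                  for t in tiny_sim.truth_transcripts
                  if t.biotype == "lncRNA"]
        assert np.mean([x for x in pp_cod if x is not None]) > \
            np.mean([x for x in pp_lnc if x is not None])

    def test_missing_rate_one_leaves_everything_unscored(self):
        cfg = small_config(conservation_missing_rate=1.0)
        genome, loci = generate_genome(cfg)
        pc, pp = generate_conservation(loci, cfg)
        for l in loci[:10]:
            t = l.to_transcript("x")
            assert transcript_conservation(t, pc) is None


class TestGroundTruthConsistency:
    def test_true_novel_subset_relations(self, tiny_sim):
        truth = tiny_sim.truth
        assert truth.true_novel_ids <= truth.true_lncRNA_ids
        assert not (truth.true_novel_ids & truth.known_lnc_ids)
        assert not (truth.true_novel_ids & truth.db_lnc_ids)
        assert not (truth.true_novel_ids & truth.noise_tx_ids)
        assert truth.true_novel_ids <= truth.consensus_ok_ids
        assert truth.true_novel_ids <= truth.covered_ids

    def test_expression_determinism(self):
        cfg = small_config()
        e1, _, _ = generate_expression(SimulationConfig(**cfg.__dict__))
        e2, _, _ = generate_expression(SimulationConfig(**cfg.__dict__))
        pd.testing.assert_frame_equal(e1, e2)
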