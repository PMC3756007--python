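"""Generator invariants: determinism, planted-label correctness, bookkeeping."""

import filecmp

import numpy as np
import pytest

from poolscan.simulate import (
    NoiseConfig,
    SimulationConfig,
    _MutableOrf,
    emit_pipeline_inputs,
    make_gene_set,
    make_outgroup,
    mutate_population_pair,
)

from conftest import STOPS, translate


def small_config(**kw):
    defaults = dict(n_genes=15, seed=3)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestMakeGeneSet:
    def test_zero_genes(self):
        assert make_gene_set(small_config(n_genes=0)) == []

    def test_orf_invariants_hold(self):
        genes = make_gene_set(SimulationConfig(n_genes=100, seed=1))
        assert len(genes) == 100
        for g in genes:
            assert g.startswith("ATG")
            assert len(g) % 3 == 0
            assert 51 <= len(g) // 3 <= 200
            assert not any(g[i : i + 3] in STOPS for i in range(0, len(g), 3))

    def test_deterministic(self):
        cfg = SimulationConfig(n_genes=30, seed=7)
        assert make_gene_set(cfg) == make_gene_set(cfg)

    def test_impossible_range_rejected(self):
        with pytest.raises(ValueError, match="impossible"):
            SimulationConfig(orf_length_codons=(100, 60)).validate()

    def test_short_minimum_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(orf_length_codons=(40, 60)).validate()


def replay_and_check(ancestor, variants):
    """Independent verification: apply each planted change in order and
    compare its recorded class against before/after translation."""
    seq = list(ancestor)
    for v in variants:
        assert seq[v.pos] == v.ref
        ci = v.pos // 3
        before = "".join(seq[3 * ci : 3 * ci + 3])
        seq[v.pos] = v.alt
        after = "".join(seq[3 * ci : 3 * ci + 3])
        expected = "synonymous" if translate(before) == translate(after) else "nonsynonymous"
        assert v.var_class == expected, v


class TestMutatePopulationPair:
    def test_zero_substitutions_identity(self):
        anc = make_gene_set(small_config(n_genes=1))[0]
        a, b, truth = mutate_population_pair(anc, 1.0, 0, seed=1)
        assert a == anc and b == anc and truth == []

    def test_invalid_omega_rejected(self):
        with pytest.raises(ValueError):
            mutate_population_pair("ATG" + "GAA" * 60, 0.0, 5)

    def test_planted_classes_verified_by_translation(self):
        anc = make_gene_set(small_config(n_genes=1, seed=5))[0]
        a, b, truth = mutate_population_pair(
            anc, 0.5, 25, seed=2, populations=("x", "y")
        )
        for pop, final in (("x", a), ("y", b)):
            branch = [v for v in truth if v.population == pop]
            replay_and_check(anc, branch)
        assert a.startswith("ATG") and b.startswith("ATG")
        for seq in (a, b):
            assert not any(seq[i:i+3] in STOPS for i in range(0, len(seq), 3))

    def test_neutral_fraction_matches_generator_site_weights(self):
        """At omega=1, kappa=1 the nonsynonymous fraction of planted changes
        matches the generator's own mutational-opportunity split within three
        binomial standard errors."""
        cfg = SimulationConfig(
            n_genes=1000, orf_length_codons=(51, 100), omega=1.0, kappa=1.0, seed=13
        )
        ancestors = make_gene_set(cfg)
        # expected nonsynonymous share from the initial weight matrices
        tot_n = tot_all = 0.0
        for anc in ancestors:
            orf = _MutableOrf(anc, 1.0, 1.0)
            n = orf.nonsyn_w.sum()
            tot_n += n
            tot_all += n + orf.syn_w.sum()
        p_expected = tot_n / tot_all

        n_subs = 10
        n_nonsyn = n_total = 0
        for i, anc in enumerate(ancestors):
            _, _, truth = mutate_population_pair(anc, 1.0, n_subs, 1.0, seed=[13, i])
            n_total += len(truth)
            n_nonsyn += sum(1 for v in truth if v.var_class == "nonsynonymous")
        assert n_total == 1000 * n_subs
        se = np.sqrt(p_expected * (1 - p_expected) / n_total)
        assert abs(n_nonsyn / n_total - p_expected) < 3 * se


class TestMakeOutgroup:
    def test_no_divergence_identity(self):
        anc = make_gene_set(small_config(n_genes=1))[0]
        seq, truth = make_outgroup(anc, 0, 0, seed=1)
        assert seq == anc and truth == []

    def test_realized_counts_near_expectation(self):
        """Planted (Dn, Ds) realized at the requested counts; classes verified
        by translation replay."""
        cfg = SimulationConfig(n_genes=200, orf_length_codons=(60, 120), seed=21)
        ancestors = make_gene_set(cfg)
        dn_total = ds_total = 0
        for i, anc in enumerate(ancestors):
            seq, truth = make_outgroup(anc, 5, 5, seed=[21, i], gene_id=f"g{i}")
            replay_and_check(anc, truth)
            dn_total += sum(1 for v in truth if v.var_class == "nonsynonymous")
            ds_total += sum(1 for v in truth if v.var_class == "synonymous")
        # requested counts are exact per gene here (no Poisson at this level)
        assert dn_total == 200 * 5
        assert ds_total == 200 * 5


class TestEmitBundle:
    def test_deterministic_bytes(self, tmp_path):
        cfg = small_config()
        b1 = emit_pipeline_inputs(cfg, tmp_path / "one")
        b2 = emit_pipeline_inputs(cfg, tmp_path / "two")
        for f1 in sorted(b1.outdir.iterdir()):
            f2 = b2.outdir / f1.name
            assert filecmp.cmp(f1, f2, shallow=False), f1.name

    def test_zero_noise_all_records_pass(self, tmp_path):
        from poolscan.io import read_vcf
        from poolscan.variants import filter_snps

        cfg = small_config(noise=NoiseConfig(0, 0, 0, 0))
        bundle = emit_pipeline_inputs(cfg, tmp_path)
        for pop in cfg.populations:
            kept, rejected = filter_snps(read_vcf(bundle.vcf[pop]))
            assert not rejected
            assert len(kept) == bundle.manifest["clean_records"][pop]

    def test_noise_counts_match_manifest(self, default_bundle):
        for pop in default_bundle.config.populations:
            text = default_bundle.vcf[pop].read_text()
            body = [l for l in text.splitlines() if l and not l.startswith("#")]
            counts = default_bundle.manifest["noise_records"][pop]
            n_clean = default_bundle.manifest["clean_records"][pop]
            assert len(body) == n_clean + sum(counts.values())
            n_indels = sum(
                1 for l in body
                if len(l.split("\t")[3]) != 1 or len(l.split("\t")[4]) != 1
            )
            assert n_indels == counts["indel"]

    def test_truth_table_matches_emitted_files(self, default_bundle):
        """Composition: per-stratum truth counts are recoverable from files."""
        import pandas as pd
        from poolscan.io import read_fasta, read_vcf

        truth = pd.read_csv(default_bundle.truth_tsv, sep="\t")
        pops = default_bundle.config.populations
        # fixed differences between populations == mismatches between FASTAs
        seqs = {
            p: {c.id: c.sequence for c in read_fasta(default_bundle.fasta[p])}
            for p in pops
        }
        n_fixed = sum(
            sum(1 for x, y in zip(seqs[pops[0]][g], seqs[pops[1]][g]) if x != y)
            for g in seqs[pops[0]]
        )
        # replay the fixed-difference rows per site to get the exact expected
        # net mismatch count (multiple hits at one site can cancel)
        state: dict = {}
        for r in truth[truth.stratum == "fixed_between_pops"].itertuples():
            key = (r.gene_id, r.contig_pos)
            if key not in state:
                state[key] = {pops[0]: r.ref, pops[1]: r.ref}
            state[key][r.population] = r.alt
        n_fixed_expected = sum(
            1 for bases in state.values() if bases[pops[0]] != bases[pops[1]]
        )
        assert n_fixed == n_fixed_expected
        # clean VCF record counts equal per-population polymorphism truth rows
        for pop in pops:
            n_poly = len(truth[truth.stratum == f"polymorphism_{pop}"])
            assert default_bundle.manifest["clean_records"][pop] == n_poly

    def test_bundle_round_trips_through_io(self, default_bundle):
        from poolscan.io import read_annotations, read_fasta, read_gff

        orfs = read_gff(default_bundle.gff)
        assert len(orfs) == default_bundle.config.n_genes
        for ann in orfs:
            start, end = default_bundle.orf_spans[ann.contig_id]
            assert (ann.start, ann.end) == (start, end)
        for pop in default_bundle.config.populations:
            contigs = read_fasta(default_bundle.fasta[pop], pop)
            assert len(contigs) == default_bundle.config.n_genes
        assert len(read_annotations(default_bundle.annotations_tsv)) == (
            default_bundle.config.n_genes
        )
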