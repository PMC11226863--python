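"""Corpus construction: filters, admixture, splitting, and the synthetic
generator's planted-usage guarantees."""

import numpy as np
import pytest

from codonmlm import (
    Cds,
    CodonUsageTable,
    ProteinSeq,
    SyntheticSpec,
    TranscriptRecord,
    compute_cai,
    filter_by_cai_mfe,
    filter_by_tpm,
    generate_synthetic_corpus,
    mix_jcat,
    train_test_split,
    translate,
)
from codonmlm.datasets import (
    DatasetSpec,
    deterministic_codon_rule,
    load_corpus,
    preprocess,
    random_usage_table,
    read_tpm_table,
    write_corpus,
)
from codonmlm.errors import (
    ConfigError,
    EmptyCorpusError,
    MfeProviderUnavailableError,
    MissingTpmError,
)
from codonmlm.evalkit import usage_frequencies, pearson_corr
from codonmlm.seqcore import AMINO_ACIDS, STANDARD_CODE


def _rec(i, cds, tpm=None):
    c = Cds(cds)
    return TranscriptRecord(id=f"r{i}", cds=c, protein=translate(c), tpm=tpm)


class TestFilters:
    def test_tpm_strictly_greater(self):
        recs = [_rec(0, "ATGAAA", 1.0), _rec(1, "ATGAAA", 5.0), _rec(2, "ATGAAA", 6.0)]
        kept = filter_by_tpm(recs, 5.0)
        assert [r.id for r in kept] == ["r2"]

    def test_threshold_zero_identity(self):
        recs = [_rec(0, "ATGAAA", 0.5), _rec(1, "ATGAAA", 2.0)]
        assert filter_by_tpm(recs, 0.0) == recs

    def test_empty_in_empty_out(self):
        assert filter_by_tpm([], 5.0) == []

    def test_missing_tpm_raises(self):
        with pytest.raises(MissingTpmError):
            filter_by_tpm([_rec(0, "ATGAAA")], 5.0)

    def test_output_is_subsequence(self):
        rng = np.random.default_rng(0)
        recs = [_rec(i, "ATGAAA", float(t)) for i, t in enumerate(rng.integers(0, 20, 30))]
        kept = filter_by_tpm(recs, 5.0)
        ids = [r.id for r in recs]
        assert [ids.index(r.id) for r in kept] == sorted(ids.index(r.id) for r in kept)

    def test_cai_filter(self, uniform_table):
        # against a skewed table, AAG-only sequences score < 1
        table = CodonUsageTable.from_counts({"AAA": 10, "AAG": 1})
        good = _rec(0, "AAAAAA")
        bad = _rec(1, "AAGAAG")
        assert compute_cai(bad.cds, table) < 0.5 < compute_cai(good.cds, table)
        kept = filter_by_cai_mfe([good, bad], table, cai_min=0.5)
        assert kept == [good]

    def test_no_bounds_identity(self, uniform_table):
        recs = [_rec(0, "ATGAAA")]
        assert filter_by_cai_mfe(recs, uniform_table) == recs

    def test_mfe_bound_without_provider(self, uniform_table):
        with pytest.raises(MfeProviderUnavailableError):
            filter_by_cai_mfe([_rec(0, "ATGAAA")], uniform_table, mfe_max=-1.0)

    def test_mfe_bound_with_provider(self, uniform_table):
        recs = [_rec(0, "ATGAAA"), _rec(1, "ATGGGG")]
        provider = lambda cds: -10.0 if "GGG" in cds.seq else 0.0
        kept = filter_by_cai_mfe(recs, uniform_table, mfe_max=-5.0, mfe_provider=provider)
        assert [r.id for r in kept] == ["r1"]


class TestMixJcat:
    @pytest.fixture()
    def corpus(self):
        return generate_synthetic_corpus(SyntheticSpec(10, (4, 8), seed=2))

    def test_proportion_zero_unchanged(self, corpus, uniform_table):
        assert mix_jcat(corpus, 0.0, uniform_table, seed=1) == corpus

    def test_proportion_one_all_cai_one(self, corpus, uniform_table):
        mixed = mix_jcat(corpus, 1.0, uniform_table, seed=1)
        assert all(compute_cai(r.cds, uniform_table) == 1.0 for r in mixed)

    def test_half_replaces_exactly_five_reproducibly(self, corpus, uniform_table):
        a = mix_jcat(corpus, 0.5, uniform_table, seed=9)
        b = mix_jcat(corpus, 0.5, uniform_table, seed=9)
        changed = [i for i, (x, y) in enumerate(zip(corpus, a)) if x.cds.seq != y.cds.seq]
        intact = [i for i, (x, y) in enumerate(zip(corpus, a)) if x.cds.seq == y.cds.seq]
        assert len(corpus) - len(changed) == len(intact)
        assert len(changed) <= 5  # some may already be optimal
        replaced_a = [r.cds.seq for r in a]
        assert replaced_a == [r.cds.seq for r in b]
        assert all(x.protein == y.protein for x, y in zip(corpus, a))

    def test_translation_conserved(self, corpus, uniform_table):
        for r in mix_jcat(corpus, 0.7, uniform_table, seed=3):
            assert translate(r.cds).seq == r.protein.seq


class TestSplit:
    def test_sizes(self, small_corpus):
        train, test = train_test_split(small_corpus, 0.2, seed=0)
        assert (len(train), len(test)) == (16, 4)

    def test_seeded_reproducible_and_exhaustive(self, small_corpus):
        a = train_test_split(small_corpus, 0.3, seed=4)
        b = train_test_split(small_corpus, 0.3, seed=4)
        assert a == b
        union = sorted(r.id for part in a for r in part)
        assert union == sorted(r.id for r in small_corpus)
        assert not set(r.id for r in a[0]) & set(r.id for r in a[1])

    def test_too_few_records(self):
        with pytest.raises(EmptyCorpusError):
            train_test_split([_rec(0, "ATGAAA")], 0.5)

    def test_bad_fraction(self, small_corpus):
        with pytest.raises(ConfigError):
            train_test_split(small_corpus, 1.0)


class TestSyntheticCorpus:
    def test_single_record_shape(self):
        recs = generate_synthetic_corpus(SyntheticSpec(1, (5, 5), seed=0))
        assert len(recs) == 1
        assert len(recs[0].protein) == 5
        assert translate(recs[0].cds).seq == recs[0].protein.seq

    def test_translation_consistency_everywhere(self, small_corpus):
        for r in small_corpus:
            assert translate(r.cds).seq == r.protein.seq

    def test_seeded_reproducibility(self):
        spec = SyntheticSpec(5, (4, 9), pair_dependence=0.4, seed=42)
        a = generate_synthetic_corpus(spec)
        b = generate_synthetic_corpus(spec)
        assert [r.cds.seq for r in a] == [r.cds.seq for r in b]

    def test_deterministic_rule_reproducible_and_rule_consistent(self):
        spec = SyntheticSpec(4, (6, 10), deterministic_rule=True, seed=8)
        recs = generate_synthetic_corpus(spec)
        for r in recs:
            prev = None
            for aa, codon in zip(r.protein.seq, r.cds.codons):
                assert codon == deterministic_codon_rule(prev, aa)
                prev = aa

    def test_degenerate_length_range(self):
        with pytest.raises(ConfigError):
            SyntheticSpec(3, (1, 1))

    def test_planted_usage_recovered_without_pair_dependence(self):
        """Law of large numbers: with no first-order dependence the
        empirical within-family frequencies converge on the planted ones
        (PCC > 0.99 at 2000 sequences)."""
        rng = np.random.default_rng(123)
        table = random_usage_table(rng)
        recs = generate_synthetic_corpus(
            SyntheticSpec(2000, (20, 40), planted_usage=table, pair_dependence=0.0, seed=77)
        )
        emp = usage_frequencies([r.cds for r in recs])
        # compare within-family conditionals, which is what is planted
        planted_cond, emp_cond = [], []
        from codonmlm.seqcore import CODONS

        for aa in AMINO_ACIDS:
            fam = STANDARD_CODE.families[aa]
            pf = np.array([table.freq[c] for c in fam]); pf /= pf.sum()
            ef = np.array([emp[CODONS.index(c)] for c in fam])
            if ef.sum() > 0:
                ef = ef / ef.sum()
            planted_cond.extend(pf); emp_cond.extend(ef)
        assert pearson_corr(np.array(planted_cond), np.array(emp_cond)) > 0.99


class TestPreprocessAndIO:
    def test_tpm_table_io(self, tmp_path):
        p = tmp_path / "tpm.tsv"
        p.write_text("id\ttpm\n# comment\nr0\t1.5\nr1\t7.25\n")
        assert read_tpm_table(p) == {"r0": 1.5, "r1": 7.25}

    def test_corpus_round_trip(self, tmp_path, small_corpus):
        write_corpus(small_corpus, tmp_path / "corpus")
        loaded = load_corpus(tmp_path / "corpus" / "cds.fasta")
        assert [r.cds.seq for r in loaded] == [r.cds.seq for r in small_corpus]
        assert [r.protein.seq for r in loaded] == [r.protein.seq for r in small_corpus]

    def test_manifest_counts_match_hand_count(self):
        """Five records with TPM {1, 3, 5, 6, 10} under threshold 5:
        exactly the 6 and the 10 survive."""
        recs = [
            _rec(0, "ATGAAA", 1.0),
            _rec(1, "ATGAAA", 3.0),
            _rec(2, "ATGAAA", 5.0),
            _rec(3, "ATGAAA", 6.0),
            _rec(4, "ATGAAA", 10.0),
        ]
        mixed, manifest = preprocess(recs, DatasetSpec(tpm_threshold=5.0))
        assert manifest["input"] == 5
        assert manifest["after_tpm"] == {"kept": 2, "dropped": 3}
        assert manifest["after_cai_mfe"] == {"kept": 2, "dropped": 0}
        assert len(mixed) == 2

    def test_filter_composition_commutes(self, uniform_table):
        recs = [_rec(i, s, t) for i, (s, t) in enumerate(
            [("AAAAAA", 6.0), ("AAGAAG", 7.0), ("ATGGGG", 2.0), ("ATGAAA", 9.0)]
        )]
        table = CodonUsageTable.from_counts({"AAA": 10, "AAG": 1})
        ab = filter_by_cai_mfe(filter_by_tpm(recs, 5.0), table, cai_min=0.5)
        ba = filter_by_tpm(filter_by_cai_mfe(recs, table, cai_min=0.5), 5.0)
        assert ab == ba
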