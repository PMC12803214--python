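"""Alignment coordinate maps, peptide-to-residue reduction, difference maps,
and the exchange-AUC stability summary."""

import numpy as np
import pytest
from scipy.optimize import minimize

from hdxstab import (
    PeptideUptakeRecord,
    ProteinEntry,
    StateTable,
    UsageError,
    ValidationError,
    build_alignment_map,
    common_coverage,
    difference_map,
    exchange_auc,
    map_interval,
    reduce_to_residues,
    reporter_residues,
)
from hdxstab.examples import synthetic_light_chain_entry


class TestAlignmentMap:
    def test_gapless_row_is_identity(self):
        entry = ProteinEntry(name="x", sequence="QSVLT", alignment_row="QSVLT")
        amap = build_alignment_map(entry)
        assert [amap.to_alignment(i) for i in range(1, 6)] == [1, 2, 3, 4, 5]

    def test_interface_peptide_alignment_to_sequential(self):
        """Alignment columns 101-110 of the AL-like entry are sequential
        residues 98-107 (three gap columns precede them)."""
        amap = build_alignment_map(synthetic_light_chain_entry())
        assert map_interval(amap, 101, 110, "aln_to_seq") == (98, 107)
        assert map_interval(amap, 98, 107, "seq_to_aln") == (101, 110)

    def test_gap_column_maps_to_nothing(self):
        amap = build_alignment_map(synthetic_light_chain_entry())
        assert amap.to_sequential(28) is None
        assert map_interval(amap, 28, 30, "aln_to_seq") is None

    def test_out_of_range_rejected(self):
        amap = build_alignment_map(synthetic_light_chain_entry())
        with pytest.raises(ValidationError):
            amap.to_sequential(500)


def _consistent_table(pattern, peptides, condition="vehicle", times=(60.0,)):
    """Build records whose %D is the reporter-mean of a residue pattern."""
    seq = "".join("ARNDQEGHILKMFSTWYV"[i % 18] for i in range(len(pattern)))
    records = []
    for start, end in peptides:
        pep = seq[start - 1 : end]
        reporters = reporter_residues(pep, start)
        pct = float(np.mean([pattern[p - 1] for p in reporters]))
        for t in times:
            records.append(
                PeptideUptakeRecord(
                    protein="x", start=start, end=end, sequence=pep,
                    condition=condition, exposure=t,
                    m0=1000.0, mt=1000.0 + pct / 10.0, mmaxD=1010.0,
                )
            )
    return StateTable(records=records, proteins=[ProteinEntry(name="x", sequence=seq)])


class TestReduction:
    def test_uniform_peptide_gives_uniform_residues(self):
        pattern = [40.0] * 12
        table = _consistent_table(pattern, [(1, 12)])
        rmap = reduce_to_residues(table)["x"]
        for pos in rmap.positions:
            assert rmap.value(pos, "vehicle", 60.0) == pytest.approx(40.0)

    @pytest.mark.parametrize("method", ["weighted_average", "nnls"])
    def test_consistency_roundtrip_uniform_signal(self, method):
        """On mutually consistent peptides drawn from a locally uniform
        residue signal, re-averaging the residue map over each peptide's
        reporters reproduces the peptide %D, and both reduction methods
        agree.  (The weighted average is a smoother: for non-uniform
        overlapping signal it trades per-peptide exactness for stability,
        which the nnls oracle test covers instead.)"""
        pattern = [35.0] * 14
        peptides = [(1, 6), (3, 10), (7, 14), (1, 14)]
        table = _consistent_table(pattern, peptides)
        rmap = reduce_to_residues(table, method)["x"]
        for rec in table.records:
            reporters = reporter_residues(rec.sequence, rec.start)
            avg = np.mean([rmap.value(p, "vehicle", 60.0) for p in reporters])
            expected = np.mean([pattern[p - 1] for p in reporters])
            assert avg == pytest.approx(expected, abs=1e-6)

    def test_nnls_reproduces_peptide_values_on_consistent_input(self):
        """nnls finds a residue pattern that reproduces every consistent
        peptide %D exactly, even when the generating pattern is non-uniform."""
        rng = np.random.default_rng(5)
        pattern = rng.uniform(10, 90, 14).tolist()
        peptides = [(1, 6), (3, 10), (7, 14), (1, 14)]
        table = _consistent_table(pattern, peptides)
        rmap = reduce_to_residues(table, "nnls")["x"]
        for rec in table.records:
            reporters = reporter_residues(rec.sequence, rec.start)
            avg = np.mean([rmap.value(p, "vehicle", 60.0) for p in reporters])
            expected = np.mean([pattern[p - 1] for p in reporters])
            assert avg == pytest.approx(expected, abs=1e-6)

    def test_nnls_matches_independent_bounded_oracle(self):
        """Bounded least squares vs an independent SLSQP minimiser on an
        8-residue toy with inconsistent (noisy) peptides."""
        rng = np.random.default_rng(9)
        pattern = rng.uniform(5, 95, 8).tolist()
        peptides = [(1, 5), (2, 8), (4, 8), (1, 8)]
        table = _consistent_table(pattern, peptides)
        # perturb the observations so the system is inconsistent
        for i, rec in enumerate(table.records):
            rec.mt += (-1) ** i * 0.3
        rmap = reduce_to_residues(table, "nnls")["x"]
        seq = table.proteins[0].sequence
        residues = sorted(
            {r for s, e in peptides for r in reporter_residues(seq[s - 1 : e], s)}
        )
        index = {r: i for i, r in enumerate(residues)}
        rows, b = [], []
        for rec in table.records:
            reps = reporter_residues(rec.sequence, rec.start)
            row = np.zeros(len(residues))
            for r in reps:
                row[index[r]] = 1.0 / len(reps)
            rows.append(row)
            b.append(10.0 * (rec.mt - rec.m0))
        A, b = np.array(rows), np.array(b)

        def objective(x):
            return float(np.sum((A @ x - b) ** 2))

        oracle = minimize(
            objective, x0=np.full(len(residues), 50.0),
            bounds=[(0.0, 100.0)] * len(residues), method="SLSQP",
            options={"maxiter": 2000, "ftol": 1e-14},
        )
        ours = np.array([rmap.value(r, "vehicle", 60.0) for r in residues])
        assert np.allclose(ours, oracle.x, atol=1e-6)

    def test_uncovered_residue_absent(self):
        table = _consistent_table([50.0] * 20, [(1, 8)])
        rmap = reduce_to_residues(table)["x"]
        assert not rmap.covered(15, "vehicle", 60.0)
        assert 15 not in rmap.positions

    def test_empty_input_rejected(self):
        with pytest.raises(UsageError):
            reduce_to_residues(StateTable(records=[]))


class TestDifferenceMap:
    def _two_condition_map(self, delta=10.0):
        pattern_a = [50.0] * 12
        pattern_b = [50.0 + delta] * 12
        ta = _consistent_table(pattern_a, [(1, 12)], condition="stabilizer")
        tb = _consistent_table(pattern_b, [(1, 12)], condition="vehicle")
        table = StateTable(records=ta.records + tb.records, proteins=ta.proteins)
        return reduce_to_residues(table)["x"]

    def test_identical_conditions_give_zero(self):
        rmap = self._two_condition_map(delta=0.0)
        dmap = difference_map(rmap, "stabilizer", "vehicle")
        assert all(v == pytest.approx(0.0) for v in dmap.delta.values())

    def test_protection_is_negative_delta(self):
        dmap = difference_map(self._two_condition_map(10.0), "stabilizer", "vehicle")
        assert all(v == pytest.approx(-10.0) for v in dmap.delta.values())

    def test_antisymmetric_under_condition_swap(self):
        rmap = self._two_condition_map(7.0)
        ab = difference_map(rmap, "stabilizer", "vehicle")
        ba = difference_map(rmap, "vehicle", "stabilizer")
        for key, v in ab.delta.items():
            assert ba.delta[key] == pytest.approx(-v)

    def test_unknown_condition_rejected(self):
        with pytest.raises(UsageError):
            difference_map(self._two_condition_map(), "stabilizer", "nope")


class TestExchangeAuc:
    def test_constant_percent_d_rectangle(self):
        """Constant 50 %D from 10 s to 16 h on log10 time: the per-residue
        area is 50 * (log10(57600) - 1) = 188.02."""
        times = (10.0, 60.0, 600.0, 3600.0, 14400.0, 57600.0)
        table = _consistent_table([50.0] * 12, [(1, 12)], times=times)
        rmap = reduce_to_residues(table)["x"]
        n_res = len(rmap.positions)
        auc = exchange_auc(rmap, "vehicle")
        per_residue = 50.0 * (np.log10(57600.0) - 1.0)
        assert auc == pytest.approx(n_res * per_residue, rel=1e-9)
        assert per_residue == pytest.approx(188.02, abs=0.01)

    def test_linear_in_percent_d(self):
        times = (10.0, 100.0, 1000.0)
        full = reduce_to_residues(_consistent_table([60.0] * 12, [(1, 12)], times=times))["x"]
        half = reduce_to_residues(_consistent_table([30.0] * 12, [(1, 12)], times=times))["x"]
        assert exchange_auc(half, "vehicle") == pytest.approx(
            exchange_auc(full, "vehicle") / 2.0
        )

    def test_single_timepoint_rejected(self):
        rmap = reduce_to_residues(_consistent_table([50.0] * 12, [(1, 12)]))["x"]
        with pytest.raises(UsageError):
            exchange_auc(rmap, "vehicle")

    def test_common_coverage_restricts_residues(self):
        times = (10.0, 100.0)
        a = reduce_to_residues(_consistent_table([50.0] * 20, [(1, 10)], times=times))["x"]
        b = reduce_to_residues(_consistent_table([50.0] * 20, [(1, 10), (9, 20)], times=times))["x"]
        shared = common_coverage([a, b])
        assert shared == sorted(set(a.positions))
        assert exchange_auc(b, "vehicle", residues=shared) == pytest.approx(
            exchange_auc(a, "vehicle", residues=shared)
        )
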