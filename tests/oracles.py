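"""Independent brute-force oracles used by several test modules."""

from mcodrates.ages import DEFAULT_AGE_BREAKS, assign_age_group
from mcodrates.weighting import CleanedRecord, assign_weights


def brute_force_counts(cleaned, scheme, age_breaks=DEFAULT_AGE_BREAKS):
    """Naive per-record double loop: assign weights, sum into strata.

    Deliberately independent of the vectorized aggregation path: it walks
    records one at a time and accumulates per-(period, sex, age band, group)
    sums in a plain dict.
    """
    part2_by_rec = {}
    for row in cleaned.part2.itertuples(index=False):
        part2_by_rec.setdefault(row.record_id, []).append((row.code, row.group))
    rec_df = cleaned.records[~cleaned.records["excluded"]]
    age_groups = assign_age_group(rec_df["age"], age_breaks).astype(str)
    sums = {}
    for row, ag in zip(rec_df.itertuples(index=False), age_groups):
        cr = CleanedRecord(
            record_id=row.record_id,
            year=int(row.year),
            month=int(row.month),
            sex=row.sex,
            age_years=int(row.age),
            ucod=row.ucod,
            ucod_group=row.ucod_group,
            excluded=False,
            part2_clean=part2_by_rec.get(row.record_id, []),
        )
        for w in assign_weights(cr, scheme):
            key = (str(cr.year), cr.sex, ag, w.group)
            sums[key] = sums.get(key, 0.0) + w.weight
    return sums
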