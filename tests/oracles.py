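"""Independent day-scan simulators used as co-payment oracles."""

def naive_outpatient_total(fees_by_day, rules):
    """Scan calendar days; accumulate fees against per-period balances."""
    paid = {}
    total = 0.0
    for day in range(0, 730):
        for fee in fees_by_day.get(day, []):
            period = day // rules.period_days
            balance = paid.get(period, 0.0)
            charge = min(fee, rules.outpatient_annual_ceiling - balance)
            charge = max(charge, 0.0)
            paid[period] = balance + charge
            total += charge
    return total


def naive_inpatient_total(night_days, rules):
    """Scan calendar days with explicit open-window state."""
    total = 0.0
    window_close = -1  # last day covered by the open window
    window_paid = 0.0
    for day in range(0, 2000):
        if day not in night_days:
            continue
        for _ in range(night_days[day]):
            if day > window_close:
                window_close = day + rules.inpatient_window_days - 1
                window_paid = 0.0
            charge = min(rules.inpatient_fee_per_night,
                         rules.inpatient_window_ceiling - window_paid)
            charge = max(charge, 0.0)
            window_paid += charge
            total += charge
    return total


def naive_drug_total(payable_by_day, rules):
    paid = {}
    total = 0.0
    for day in sorted(payable_by_day):
        for amount in payable_by_day[day]:
            period = day // rules.period_days
            balance = paid.get(period, 0.0)
            charge = min(amount, max(rules.drug_annual_ceiling - balance, 0.0))
            paid[period] = balance + charge
            total += charge
    return total
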