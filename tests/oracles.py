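"""Independent longhand oracles, written as straight-line arithmetic.

These deliberately share no code with the package: each formula is
re-typed from its printed form using only the standard library, so a
transcription error in the package and in the oracle would have to
coincide to go unnoticed.
"""

import math
import statistics


def tanaka_oracle(age, weight, height):
    return (-2.04) * age + 14.89 * weight + 16.14 * height - 2244.45


def kawasaki_male_oracle(age, weight, height):
    return 12.63 * age + 15.12 * weight + 7.39 * height - 79.9


def kawasaki_female_oracle(age, weight, height):
    return (-4.72) * age + 8.58 * weight + 5.09 * height - 74.5


def mage_oracle(age, weight, height, bmi, black, female):
    if female:
        k, b1, b2 = 0.00163, 1.429, 0.0198
    else:
        k, b1, b2 = 0.00179, 1.366, 0.0159
    lean = math.pow(weight, 1.5) * math.sqrt(height)
    race = 1.0 + 0.18 * black * (b1 - b2 * bmi)
    return k * (140.0 - age) * lean * race


def pruie_oracle(uic_ug_l, ucr_mg_dl, prcr_mg_day):
    # spot iodine per mg creatinine, times daily creatinine
    ucr_mg_l = ucr_mg_dl * 10.0
    return (uic_ug_l / ucr_mg_l) * prcr_mg_day


def iom_intake_oracle(uic_ug_l, weight_kg):
    daily_volume_l = 0.0009 * 24.0 * weight_kg
    return (uic_ug_l / 0.92) * daily_volume_l


def intake_oracle(uie_ug_day):
    return uie_ug_day / 0.92


def kappa_oracle(a, b, c, d):
    # expand the table to label vectors and count agreement by hand
    n = a + b + c + d
    po = (a + d) / n
    p_pred_below = (a + b) / n
    p_meas_below = (a + c) / n
    pe = p_pred_below * p_meas_below + (1 - p_pred_below) * (1 - p_meas_below)
    return (po - pe) / (1 - pe)


def bland_altman_oracle(pred, meas, z=1.96):
    d = [math.log(p) - math.log(m) for p, m in zip(pred, meas)]
    mean_d = statistics.fmean(d)
    sd_d = statistics.stdev(d)
    return (
        math.exp(mean_d) * 100.0,
        math.exp(mean_d - z * sd_d) * 100.0,
        math.exp(mean_d + z * sd_d) * 100.0,
    )
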