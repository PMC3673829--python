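"""Baseline projection of adult type 2 diabetes burden in Syria, 2003–2022.

Reconstructs the age/sex population denominators from the published burden
table, initializes the 2003 compartments from the survey prevalences, runs
19 annual Markov cycles under the published risk-factor trend rules, and
prints the headline figures: prevalence roughly doubles while the number
of people with diabetes roughly quadruples, driven jointly by population
growth/aging and the rising obesity trend.
"""

from dmproj import run_projection, syria
from dmproj.reporting import idf_comparable, relative_increase, tabulate

result = run_projection(syria.projection_config())

print("Overall 25+ prevalence and cases:")
for year in (2003, 2006, 2011, 2022):
    print(
        f"  {year}: {100 * result.prevalence(year):5.1f}%   "
        f"{result.diabetes_count(year):>12,.0f} people"
    )

for sex, label in ((None, "total"), ("M", "men"), ("F", "women")):
    rel = relative_increase(
        100 * result.prevalence(2003, sex), 100 * result.prevalence(2022, sex)
    )
    print(f"Relative prevalence increase 2003–2022 ({label}): {rel:.1f}%")

print("\nBurden table (count of people with diabetes, prevalence % in parentheses):")
print(tabulate(result, [2003, 2011, 2022]).to_string(index=False))

idf = idf_comparable(result, syria.population_20_24(), syria.SPLIT_75_79)
p_2079 = 100 * idf.query("year == 2022 and sex == 'T'").prevalence.iloc[0]
print(
    f"\n20–79 comparison window, 2022: {p_2079:.1f}% "
    "(adding a diabetes-free 20–24 band and dropping ages 80+ dilutes the 25+ figure)"
)
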