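# 2013 European standard population, aggregated to the five adult age
# groups used in the analysis (per 100,000 total standard population;
# adults 20+ sum to 78,500). Source: Eurostat, Revision of the European
# Standard Population (2013).
age_group,standard_population
20-44,32500
45-64,26500
65-74,10500
75-84,6500
85+,2500
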