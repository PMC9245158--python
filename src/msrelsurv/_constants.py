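"""Shared numeric conventions.

All follow-up time is measured in days since study entry; demographic
(age / calendar) arithmetic uses the same year length as established
relative-survival ratetables.
"""

#: Days per year used for every age/calendar-time conversion.
DAYS_PER_YEAR: float = 365.241

#: Oldest attained age (years) the death-time sampler will search before
#: declaring that a table cannot produce a death (returns +inf).
MAX_ATTAINED_YEARS: int = 200
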