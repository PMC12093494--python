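"""Hypothesis strategies for domain hits and family labels."""

from hypothesis import strategies as st

from cazprofiler.domtblout import DomainHit
from cazprofiler.vocab import Category, FamilyLabel

family_labels = st.builds(
    FamilyLabel,
    category=st.sampled_from(list(Category)),
    family_number=st.integers(min_value=1, max_value=200),
    subfamily=st.one_of(st.none(), st.integers(min_value=0, max_value=60)),
)


@st.composite
def domain_hits(draw, protein_id=None, organism_tag="orgX"):
    pid = protein_id if protein_id is not None else draw(
        st.from_regex(r"p[0-9]{1,5}", fullmatch=True)
    )
    hmm_length = draw(st.integers(min_value=10, max_value=800))
    hmm_from = draw(st.integers(min_value=1, max_value=hmm_length))
    hmm_to = draw(st.integers(min_value=hmm_from, max_value=hmm_length))
    ali_from = draw(st.integers(min_value=1, max_value=2000))
    ali_to = draw(st.integers(min_value=ali_from, max_value=ali_from + 1200))
    env_from = draw(st.integers(min_value=max(1, ali_from - 5), max_value=ali_from))
    env_to = draw(st.integers(min_value=ali_to, max_value=ali_to + 5))
    ievalue = draw(
        st.floats(min_value=1e-100, max_value=1.0, allow_nan=False, allow_infinity=False)
    )
    return DomainHit(
        protein_id=pid,
        organism_tag=organism_tag,
        family=draw(family_labels),
        hmm_length=hmm_length,
        hmm_from=hmm_from,
        hmm_to=hmm_to,
        ali_from=ali_from,
        ali_to=ali_to,
        env_from=env_from,
        env_to=env_to,
        full_seq_evalue=ievalue,
        dom_ievalue=ievalue,
        dom_score=draw(st.floats(min_value=-10.0, max_value=1000.0, allow_nan=False)),
    )
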