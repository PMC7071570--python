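# Default English smoking-status pattern lexicon.
#
# This lexicon is an editable approximation built from common Canadian
# primary-care EMR phrasings; the production lexicon used by the national
# network was derived from manual review of its own records and is not
# public.  Patterns are matched case-insensitively on normalized text with
# letter boundaries (so "ppd" fires inside "2ppd" but "no" does not fire
# inside "non").  One block per assignable category; order within a block
# is documentation order only.
language: en
relationship_words:
  - aunt
  - uncle
  - father
  - mother
  - brother
  - sister
  - husband
  - wife
  - son
  - daughter
  - grandmother
  - grandfather
  - grandma
  - grandpa
  - mom
  - dad
  - parent
  - parents
  - family
  - spouse
  - partner
  - cousin
  - niece
  - nephew
patterns:
  current:
    - current
    - smoker
    - smokes
    - "yes"
    - ppd
    - packs/day
    - pack/day
    - packs per day
    - cigarettes/day
    - cigs/day
  past:
    - past
    - ex-smoker
    - ex smoker
    - former
    - quit
  never:
    - never
  not_current:
    - non-smoker
    - non smoker
    - nonsmoker
    - "no"
    - not current
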