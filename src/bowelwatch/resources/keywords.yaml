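# Editable keyword lists driving the account-type rule cascade.
# These are seed lists (the rules match whole lowercase tokens); extend them
# to tighten or broaden the cascade for a particular corpus.
nonpersonal:
  - official
  - news
  - info
  - pharma
  - foundation
  - charity
  - association
  - society
  - organization
  - organisation
  - company
  - clinic
  - hospital
  - network
  - trust
  - journal
  - magazine
first_person_pronouns:
  - i
  - me
  - my
  - mine
  - myself
  - im
  - ive
  - we
  - us
  - our
  - ours
  - ourselves
person_abbreviations:
  - mr
  - mrs
  - ms
  - miss
  - mx
expert:
  - dr
  - doctor
  - prof
  - professor
  - md
  - phd
  - researcher
  - gastroenterologist
  - dietitian
  - nutritionist
  - nurse
  - rd
  - rn
url_domains:
  - .org
  - .com
  - .net
  - .gov
  - .edu
  - .info
country_codes:
  - uk
  - usa
  - us
  - eu
  - ca
  - au
  - nz
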