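# Psychosocial-effects theme keyword lexicon (built-in default).
# One theme per [bracketed] header, one keyword (root or phrase) per line.
[Psychological]
psychological
psychology
[Fatigue]
fatigue
tired
tiring
fatiguing
exhaust
nap
rest
[Stress]
stress
stressed
[Posttraumatic stress]
posttraumatic stress
trauma
traumatized
[Posttraumatic growth]
posttraumatic growth
trauma
traumatized
[Distress]
distress
depression
depressed
feel down
feeling down
sad
sadness
tear
cry
upset
heartbroken
heartbreaking
wrench
guilt
cried
[Anxiety]
anxiety
anxious
panic
[Fear of recurrences]
fear of recurrence
recurrence
[Sleep disturbances]
sleep
insomnia
wake
asleep
disturb
restless
sleep disturbance
[Coping]
coping
cope
coped
[Worry]
worry
worried
worrying
worries
[Illness intrusiveness]
lifestyle
intruding
illness intrusiveness
interfere
embarrass
ashamed
shame
disrupt
[Cognitive changes]
fog
memory
concentrate
concentrating
concentration
cognitive
cognition
foggy
[Educational problems]
educational problem
student
learning difficult
problems in school
[Social withdrawal]
social withdraw
withdraw socially
social isolation
socially isolating
lonely
social withdrawal
[Financial and employment]
financial
finances
employ
job
fulltime
full-time
part-time
workload
[Financial toxicity]
financial toxicity
debt
cost
bill
expensive
expense
money
money trouble
financial trouble
[Underemployment, unemployment, and return to work]
underemploy
unemploy
return to work
return fulltime
return full-time
return part-time
laid off
lay off
fire
quit
fired
[Work productivity]
work productivity
productive at work
working hard
work hard
falling behind
fall behind
fell behind
[School productivity]
school productivity
learning
school college
[Insurance status]
insurance
insured
medicaid
medicare
copay
[Interpersonal]
interpersonal
boyfriend
husband
spouse
girlfriend
wife
significant other
fiancé
partner
relationship
[Sexuality and intimacy]
sex
intimacy
intimate
intercourse
sexuality
sexual
[Fertility]
fertility
fertile
infertility
infertile
preservation
pregnancy
pregnant
conceiving
conceive
miscarriage
miscarry
ivf
in vitro
oocyte
embryo
freeze
froze
egg
sperm
frozen
[Family and caregiver relationships]
mother
mom
father
dad
sister
brother
son
daughter
friend
spouse
husband
wife
partner
kid
child
family
caregiver
relationship
friendship
partnership
marriage
divorce
separate
engage
fiancé
[Recommended evaluation provided (eg, laboratory testing, imaging, or referral to specialty care)]
psychological evaluation
social history
referral to a therapist
referral to a psych
referral to psych
social work referral
referral to social work
referred to social work
referred to a social work
referred to a psych
[Treatment provided (eg, medication, therapy, or exercise)]
psychological treatment
psychological medication
counseling
therapy
support group
zoloft
xanax
lexapro
celexa
wellbutrin
desyrel
prozac
adderall
ativan
cymbalta
effexor
seroquel
depakote
[Assessment of adherence to treatment completed]
adherence
adhere
as instructed
stick to
stuck with
[Reassessment of symptoms and conditions at defined intervals or treatment phases]
reassessment of psychological symptoms
reassess psychological symptoms
review psychological symptoms
reviewed psychological symptoms
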