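# Packaged toy English lexicon (swappable via PrepConfig.lexicon).
a
about
account
action
activity
advances
age
air
alarming
and
animals
announcement
area
arm
art
article
at
babies
back
backlash
bacteria
body
book
boy
breakfast
breakthrough
building
business
car
care
case
celebrates
cells
center
change
child
city
class
coffee
college
community
company
computer
condemns
control
cost
country
couple
court
covers
crispr
criticizes
crops
dangerous
data
date
day
death
decision
describes
development
device
difference
dinner
director
discusses
disease
dna
doctor
door
drinking
drug
earlier
editing
education
effect
effort
embryo
embryos
end
energy
event
exciting
experience
expert
explainer
eye
face
fact
family
fast
father
fear
field
figure
food
foot
football
for
force
form
friend
friends
future
game
garden
gene
genome
germline
girl
government
great
ground
group
guy
had
hails
hand
head
health
heart
history
home
hope
hospital
hour
house
humans
id
idea
image
in
industry
information
interest
is
issue
job
just
kind
laboratories
law
leader
level
life
lifesaving
light
line
livestock
long
lot
lovely
lunch
man
market
matter
media
member
mice
microbes
mind
minute
model
moment
money
month
morning
mother
movie
music
mutation
name
nation
nature
need
negative
network
neutral
new
news
night
number
office
official
oil
online
organism
others
outlook
outside
overview
paper
parent
part
party
pasta
patients
people
person
phage
phone
place
plan
plants
player
pleasant
point
police
policy
position
positive
power
president
price
problem
process
program
progress
project
promising
public
question
questions
rate
reason
record
relationship
relevance
relevant
remarkable
report
research
result
reviews
rice
right
risk
road
role
room
safety
say
scandal
school
science
scientists
season
sense
sentiment
sequence
service
show
side
site
situation
society
son
space
spreading
star
state
story
street
student
study
success
summary
system
table
tax
teacher
team
tech
technology
tennis
terrible
test
text
the
therapy
thing
this
time
today
tonight
town
treatment
tree
trial
unethical
update
use
user
value
video
view
voice
volunteers
walk
war
warning
warns
water
way
weather
week
welcomes
whole
wife
with
woman
word
work
world
year
yesterday
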